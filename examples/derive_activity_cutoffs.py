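"""Derive rule-in / rule-out activity cut-offs from labeled fibroblast data.

The lower cut-off is the largest observed activity below which only Hurler
patients occur (perfect rule-in specificity); the upper cut-off is the
largest observed Hurler activity (perfect rule-out sensitivity). Values in
between form the gray zone that the clinical step must resolve.
"""

from mpsi_predict import derive_thresholds, load_reference_cohort, roc_auc

cohort = load_reference_cohort()
sub = [r for r in cohort if r.idua_activity is not None]
activities = [r.idua_activity for r in sub]
labels = [r.is_hurler for r in sub]

curve = roc_auc(activities, labels)
print(f"{len(sub)} labeled activities ({sum(labels)} Hurler); "
      f"ROC AUC = {curve.auc:.3f} (pair counting, low activity = Hurler)")

zone = derive_thresholds(activities, labels)
t = zone.thresholds
print(f"derived cut-offs: lower {t.lower:g}, upper {t.upper:g} nmol·mg⁻¹·hr⁻¹")
print(f"rule-in  (<= {t.lower:g} -> H):    sensitivity {zone.rule_in_sensitivity:.0%}, "
      f"specificity {zone.rule_in_specificity:.0%}")
print(f"rule-out (> {t.upper:g} -> non-H): sensitivity {zone.rule_out_sensitivity:.0%}, "
      f"specificity {zone.rule_out_specificity:.0%}")
print(f"{zone.n_intermediate} samples fall in the gray zone and need the clinical step.")
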