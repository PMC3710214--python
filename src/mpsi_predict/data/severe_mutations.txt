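# IDUA alleles reported in the literature to predict a Hurler (MPS I-H)
# phenotype when present in homozygous or compound-heterozygous form.
# One allele per line; "#" starts a comment.
# Nonsense
p.W41X
p.Y64X
p.Q60X
p.Q63X
p.Q70X
p.P201X
p.E274X
p.Q310X
p.Y343X
p.W402X
p.E404X
p.Q561X
p.Y581X
p.Q584X
p.R619X
p.R621X
p.W626X
# Missense / splice / indel
p.G51D
c.134del12
p.G208V
p.L218P
p.A327P
p.T366P
c.704ins5
c.1190-1G>A
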