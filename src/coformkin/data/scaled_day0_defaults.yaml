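# Scaled day-0 residues (mg/kg at a substance application rate of
# 1 kg/ha) per crop group: median and 90th percentile of published
# supervised-residue-trial compilations.  "leaf lettuce" / "head
# lettuce" alias the lettuce group; parsley has no published entry and
# borrows the lettuce values as a surrogate (flagged on lookup).
# Users may extend or replace this table via their own YAML file.
leek: {median: 5.1, p90: 6.9}
lettuce: {median: 19, p90: 70}
leaf lettuce: {median: 19, p90: 70}
head lettuce: {median: 19, p90: 70}
apples: {median: 0.8, p90: 2.6}
parsley: {median: 19, p90: 70, surrogate_for: lettuce}
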