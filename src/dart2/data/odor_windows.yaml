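# Steady-state averaging windows per odor, in minutes from odor application.
# Each odor reaches its maximal, approximately steady response on its own
# schedule, so the averaging window is part of the assay definition.
benzaldehyde: [20, 60]
propionic acid: [5, 25]
r-limonene: [0, 60]
aitc: [20, 60]
citronellal: [20, 60]
isovaleric acid: [5, 25]
lemongrass: [20, 60]
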