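# Default reference anchors: the five human SMYD proteins plus the
# Drosophila melanogaster catalog with its class/subgroup assignments.
# Columns: id <tab> class <tab> subgroup (optional).
# The subgroup identities of CG8378 (Smyd4I) and CG7759 (Smyd4L) are
# inferences from group counts and expression pairing, not direct
# statements; override with a custom anchor file if needed.
id	class	subgroup
HsSMYD1	SMYD3	SMYD1
HsSMYD2	SMYD3	SMYD2
HsSMYD3	SMYD3	SMYD3
HsSMYD4	SMYD4	SMYD4
HsSMYD5	SMYD5
DmCG13761	SMYD3	SMYD3
DmCG1868	SMYD4	SMYD4
DmCG14122	SMYD4	SMYD4L
DmCG7759	SMYD4	SMYD4L
DmCG8378	SMYD4	SMYD4I
DmCG3353	SMYD5
DmCG8503	SMYDA
DmCG18136	SMYDA
DmCG43129	SMYDA
DmCG11160	SMYDA
DmCG14590	SMYDA
DmCG9642	SMYDA
DmCG9640	SMYDA
DmCG33548	SMYDA
DmCG12119	SMYDA
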