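# default interaction-keyword list (whole-token, case-insensitive matching;
# hyphen-split subtokens count, so "BCG-induced" matches "induced")
activate
activates
activated
activation
bind
binds
bound
binding
block
blocks
blocked
induce
induces
induced
induction
inhibit
inhibits
inhibited
inhibition
interact
interacts
interacted
interaction
mediate
mediates
mediated
phosphorylate
phosphorylates
phosphorylated
regulate
regulates
regulated
regulation
stimulate
stimulates
stimulated
stimulation
suppress
suppresses
suppressed
suppression
up-regulate
up-regulates
up-regulated
upregulate
upregulates
upregulated
down-regulate
down-regulates
down-regulated
downregulate
downregulates
downregulated
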