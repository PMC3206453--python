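Add
ApparatusAction
Concentrate
Cool
Degass
Dissolve
Dry
Extract
Filter
Heat
Partition
Precipitate
Purify
Quench
Recover
Remove
Stir
Synthesize
Wait
Wash
Yield
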