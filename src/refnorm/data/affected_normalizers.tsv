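# Genes/proteins commonly used for normalization that have been reported as
# differentially expressed following lithium treatment or in mood-disorder
# tissue (microarray and proteomics evidence).
# Columns: gene = canonical symbol; context = where the alteration was seen.
gene	context
Actb	lithium-treated mouse brain mRNA (+7.479); lithium-treated rat IMCD protein (+1.7); BD/SCZ hippocampus protein; ischemia synaptosomes
Gapdh	lithium-treated rat PFC synaptosomes mRNA (down); lithium-treated rat PFC protein (-1.27); ischemia synaptosomes (+2.4)
Tuba	MDD/SCZ cortex protein; lithium-treated rat brain mRNA (+2.2); lithium-treated mouse brain mRNA (Tuba4 +1.3, Tuba8 +1.67)
Tubb	BD cortex/hippocampus protein; lithium-treated rat PFC synaptosomes mRNA (down); lithium-treated mouse FC protein (Tubb3/4/5)
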