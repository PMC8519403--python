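name	pattern	category	citation
E-box	CANNTG	other	Toledo-Ortiz et al. 2003, Plant Cell 15:1749 (CANNTG core recognized by bHLH proteins)
G-box	CACGTG	light	Giuliano et al. 1988, PNAS 85:7089 (palindromic G-box variant of the E-box)
ABRE	ACGTGKC	hormone	Hattori et al. 2002, Plant Cell Physiol 43:136 (ABA-responsive element core)
LTR	CCGAAA	stress	Baker et al. 1994, Plant Mol Biol 24:701 (low-temperature-responsive element of barley blt4.9)
MBS	CAACTG	stress	Urao et al. 1993, Plant Cell 5:1529 (MYB binding site linked to drought induction)
ARE	AAACCA	stress	Walker et al. 1987, PNAS 84:6624 (anaerobic-response element core)
TGACG-motif	TGACG	hormone	Liu et al. 1994, Plant Cell 6:645 (as-1-type MeJA/SA-responsive element)
GCN4_motif	TGAGTCA	development	Onodera et al. 2001, J Biol Chem 276:14139 (endosperm-expression element)
I-box	GATAAG	light	Giuliano et al. 1988, PNAS 85:7089 (light-regulated promoter element)
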