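flow_id	description	value_mgC_m2_d
gpp-ph3	Microphytoplankton gross primary production	509.35
gpp-ph2	Nanophytoplankton gross primary production	66.62
gpp-ph1	Picophytoplankton gross primary production	100.28
ph3-res	Microphytoplankton respiration	192.25
ph3-doc	Microphytoplankton doc excretion	39.10
ph3-mic	Microphytoplankton grazing by mic	13.25
ph3-mes	Microphytoplankton grazing by mes	11.89
ph3-spg	Parasitism of ph3 by sporangia	187.44
ph3-det	Microphytoplankton det production	15.50
ph3-los	Microphytoplankton sinking	49.92
ph2-res	Nanophytoplankton respiration	4.29
ph2-doc	Nanophytoplankton doc excretion	6.63
ph2-mic	Nanophytoplankton grazing by mic	35.74
ph2-mes	Nanophytoplankton grazing by mes	18.53
ph2-los	Nanophytoplankton sinking	0.74
ph2-det	Nanophytoplankton det production	0.70
ph1-res	Picophytoplankton respiration	19.86
ph1-doc	Picophytoplankton doc excretion	23.92
ph1-hnf	Picophytoplankton grazing by hnf	34.57
ph1-mic	Picophytoplankton grazing by mic	16.60
ph1-mes	Picophytoplankton grazing by mes	5.34
bac-res	Bacteria respiration	98.85
bac-hnf	Bacterivory by hnf	66.39
bac-mes	Bacteria uptake by mes	20.74
bac-mic	Bacteria uptake by mic	6.47
bac-doc	Bacterial doc release due to virus lysis	9.90
bac-det	Attached bacteria to det	2.09
hnf-res	Heterotrophic nanoplankton respiration	38.12
hnf-doc	Heterotrophic nanoplankton doc excretion	21.56
hnf-mic	Heterotrophic nanoplankton uptake by mic	13.97
hnf-mes	Heterotrophic nanoplankton uptake by mes	14.65
hnf-det	Heterotrophic nanoplankton det production	12.66
mic-res	Microzooplankton respiration	47.82
mic-doc	Microzooplankton doc excretion	29.85
mic-mes	Microzooplankton uptake by mes	73.64
mic-det	Microzooplankton egestion	19.85
mic-los	Microzooplankton sinking	2.54
mes-res	Mesozooplankton respiration	48.57
mes-doc	Mesozooplankton doc excretion	30.49
mes-det	Mesozooplankton egestion	20.29
mes-los	Mesozooplankton grazing by larger organisms	78.64
spg-res	Sporangia respiration	32.93
spg-zsp	Sporangia emission of zoospores	140.45
spg-det	Sporangia detrital production	3.75
spg-los	Sporangia sinking	10.31
zsp-res	Zoospores respiration	24.46
zsp-mic	Zoospores ingestion by mic	87.68
zsp-mes	Zoospores ingestion by mes	19.92
zsp-det	Zoospores detrital production	8.40
doc-bac	Dissolved organic carbon uptake by bacteria	204.45
det-doc	Detritus dissolution	43.00
det-mes	Detritus consumption by mes	13.29
det-los	Detritus sinking	26.95
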