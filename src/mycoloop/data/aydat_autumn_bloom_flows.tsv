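flow_id	description	value_mgC_m2_d
gpp-ph3	Microphytoplankton gross primary production	2243.38
gpp-ph2	Nanophytoplankton gross primary production	253.91
gpp-ph1	Picophytoplankton gross primary production	22.70
ph3-res	Microphytoplankton respiration	112.62
ph3-doc	Microphytoplankton doc excretion	193.94
ph3-mic	Microphytoplankton grazing by mic	0.26
ph3-mes	Microphytoplankton grazing by mes	64.05
ph3-spg	Parasitism of ph3 by sporangia	746.00
ph3-det	Microphytoplankton det production	228.93
ph3-los	Microphytoplankton sinking	897.58
ph2-res	Nanophytoplankton respiration	15.42
ph2-doc	Nanophytoplankton doc excretion	24.20
ph2-mic	Nanophytoplankton grazing by mic	184.98
ph2-mes	Nanophytoplankton grazing by mes	26.69
ph2-los	Nanophytoplankton sinking	2.48
ph2-det	Nanophytoplankton det production	0.14
ph1-res	Picophytoplankton respiration	2.58
ph1-doc	Picophytoplankton doc excretion	3.16
ph1-hnf	Picophytoplankton grazing by hnf	16.53
ph1-mic	Picophytoplankton grazing by mic	0.18
ph1-mes	Picophytoplankton grazing by mes	0.26
bac-res	Bacteria respiration	327.02
bac-hnf	Bacterivory by hnf	63.02
bac-mes	Bacteria uptake by mes	26.63
bac-mic	Bacteria uptake by mic	109.40
bac-doc	Bacterial doc release due to virus lysis	0.71
bac-det	Attached bacteria to det	44.00
hnf-res	Heterotrophic nanoplankton respiration	27.37
hnf-doc	Heterotrophic nanoplankton doc excretion	14.55
hnf-mic	Heterotrophic nanoplankton uptake by mic	14.74
hnf-mes	Heterotrophic nanoplankton uptake by mes	14.78
hnf-det	Heterotrophic nanoplankton det production	8.11
mic-res	Microzooplankton respiration	255.55
mic-doc	Microzooplankton doc excretion	145.81
mic-mes	Microzooplankton uptake by mes	105.98
mic-det	Microzooplankton egestion	73.33
mic-los	Microzooplankton sinking	151.10
mes-res	Mesozooplankton respiration	93.11
mes-doc	Mesozooplankton doc excretion	50.08
mes-det	Mesozooplankton egestion	26.57
mes-los	Mesozooplankton grazing by larger organisms	94.42
spg-res	Sporangia respiration	74.86
spg-zsp	Sporangia emission of zoospores	504.12
spg-det	Sporangia detrital production	0.15
spg-los	Sporangia sinking	166.86
zsp-res	Zoospores respiration	56.94
zsp-mic	Zoospores ingestion by mic	421.87
zsp-mes	Zoospores ingestion by mes	25.15
zsp-det	Zoospores detrital production	0.15
doc-bac	Dissolved organic carbon uptake by bacteria	570.78
det-doc	Detritus dissolution	138.34
det-mes	Detritus consumption by mes	0.65
det-mic	Detritus consumption by mic	0.35
det-los	Detritus sinking	242.06
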