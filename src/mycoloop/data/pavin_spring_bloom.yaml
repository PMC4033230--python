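# Spring diatom bloom food web of a deep oligo-mesotrophic lake, with chytrid
# parasite compartments (host-attached sporangia spg, free-living zoospores zsp).
# 53 carbon flows; all values mgC m-2 d-1.
name: pavin_spring_bloom
compartments:
  - {id: ph1, name: picophytoplankton (0.2-2 um), kind: living, tags: [autotroph]}
  - {id: ph2, name: nanophytoplankton (2-20 um), kind: living, tags: [autotroph]}
  - {id: ph3, name: microphytoplankton (20-150 um, bloom diatoms), kind: living, tags: [autotroph]}
  - {id: bac, name: heterotrophic bacteria, kind: living, tags: [heterotroph]}
  - {id: hnf, name: heterotrophic nanoflagellates, kind: living, tags: [heterotroph]}
  - {id: mic, name: microzooplankton (ciliates, small rotifers), kind: living, tags: [heterotroph]}
  - {id: mes, name: mesozooplankton (cladocerans, copepods), kind: living, tags: [heterotroph]}
  - {id: spg, name: chytrid sporangia on ph3 hosts, kind: living, tags: [heterotroph, parasite-sporangia]}
  - {id: zsp, name: free-living chytrid zoospores, kind: living, tags: [heterotroph, parasite-zoospore]}
  - {id: det, name: detritus, kind: nonliving, tags: [detrital]}
  - {id: doc, name: dissolved organic carbon, kind: nonliving, tags: [detrital]}
flows:
  - gpp-ph3
  - gpp-ph2
  - gpp-ph1
  - ph3-res
  - ph3-doc
  - ph3-mic
  - ph3-mes
  - ph3-spg
  - ph3-det
  - ph3-los
  - ph2-res
  - ph2-doc
  - ph2-mic
  - ph2-mes
  - ph2-los
  - ph2-det
  - ph1-res
  - ph1-doc
  - ph1-hnf
  - ph1-mic
  - ph1-mes
  - bac-res
  - bac-hnf
  - bac-mes
  - bac-mic
  - bac-doc
  - bac-det
  - hnf-res
  - hnf-doc
  - hnf-mic
  - hnf-mes
  - hnf-det
  - mic-res
  - mic-doc
  - mic-mes
  - mic-det
  - mic-los
  - mes-res
  - mes-doc
  - mes-det
  - mes-los
  - spg-res
  - spg-zsp
  - spg-det
  - spg-los
  - zsp-res
  - zsp-mic
  - zsp-mes
  - zsp-det
  - doc-bac
  - det-doc
  - det-mes
  - det-los
equalities:
  - {label: total gross primary production, expr: GPP, value: 676.25}
  - {label: total net primary production, expr: NPP, value: 459.85}
  - {label: net bacterial production, expr: doc-bac - bac-res, value: 105.60}
  - {label: viral lysis of bacteria, expr: bac-doc, value: 9.90}
constraints:
  - {label: ph3 share of gross primary production, expr: gpp-ph3, min: 0.60 * GPP, max: 0.85 * GPP}
  - {label: ph2 share of gross primary production, expr: gpp-ph2, min: 0.02 * GPP, max: 0.10 * GPP}
  - {label: ph1 share of gross primary production, expr: gpp-ph1, min: 0.05 * GPP, max: 0.20 * GPP}
  - {label: ph1 respiration vs own production, expr: ph1-res, min: 0.05 * gpp-ph1, max: 0.30 * gpp-ph1}
  - {label: ph2 respiration vs own production, expr: ph2-res, min: 0.05 * gpp-ph2, max: 0.30 * gpp-ph2}
  - {label: ph3 respiration vs own production, expr: ph3-res, min: 0.05 * gpp-ph3, max: 0.40 * gpp-ph3}
  - {label: bacterial respiration vs doc uptake, expr: bac-res, min: 0.20 * doc-bac}
  - {label: hnf respiration vs ingestion, expr: hnf-res, min: 0.20 * Ing(hnf)}
  - {label: mic respiration vs ingestion, expr: mic-res, min: 0.20 * Ing(mic)}
  - {label: mes respiration vs ingestion, expr: mes-res, min: 0.20 * Ing(mes)}
  - {label: sporangia respiration vs carbon input, expr: spg-res, max: 0.20 * Ing(spg)}
  - {label: zoospore respiration vs carbon input, expr: zsp-res, max: 0.20 * Ing(zsp)}
  - {label: ph1 exudation vs own net production, expr: ph1-doc, min: 0.10 * NPP(ph1), max: 0.55 * NPP(ph1)}
  - {label: ph2 exudation vs own net production, expr: ph2-doc, min: 0.10 * NPP(ph2), max: 0.55 * NPP(ph2)}
  - {label: ph3 exudation vs own net production, expr: ph3-doc, min: 0.10 * NPP(ph3), max: 0.55 * NPP(ph3)}
  - {label: hnf excretion floor and respiration cap, expr: hnf-doc, min: 0.10 * Ing(hnf), max: hnf-res}
  - {label: mic excretion floor and respiration cap, expr: mic-doc, min: 0.10 * Ing(mic), max: mic-res}
  - {label: mes excretion floor and respiration cap, expr: mes-doc, min: 0.10 * Ing(mes), max: mes-res}
  - {label: hnf net growth efficiency, expr: Ing(hnf) - hnf-res - hnf-doc - hnf-det, min: 0.25 * Ing(hnf), max: 0.50 * Ing(hnf)}
  - {label: mic net growth efficiency, expr: Ing(mic) - mic-res - mic-doc - mic-det, min: 0.25 * Ing(mic), max: 0.50 * Ing(mic)}
  - {label: mes net growth efficiency, expr: Ing(mes) - mes-res - mes-doc - mes-det, min: 0.25 * Ing(mes), max: 0.50 * Ing(mes)}
  - {label: bacterial growth efficiency (loss form), expr: bac-res + bac-doc + bac-det, min: 0.50 * doc-bac, max: 0.75 * doc-bac}
  - {label: hnf assimilation efficiency, expr: Ing(hnf) - hnf-det, min: 0.50 * Ing(hnf), max: 0.90 * Ing(hnf)}
  - {label: mic assimilation efficiency, expr: Ing(mic) - mic-det, min: 0.50 * Ing(mic), max: 0.90 * Ing(mic)}
  - {label: mes assimilation efficiency, expr: Ing(mes) - mes-det, min: 0.50 * Ing(mes), max: 0.90 * Ing(mes)}
  - {label: mes grazing on ph3 vs ph3 net production, expr: ph3-mes, min: 0.03 * NPP(ph3), max: 0.07 * NPP(ph3)}
  - {label: mic share cap of mes ingestion, expr: mic-mes, max: 0.80 * Ing(mes)}
  - {label: mes diet bac share, expr: bac-mes, min: 0.10 * Ing(mes), max: 0.15 * Ing(mes)}
  - {label: mes diet ph2 share, expr: ph2-mes, min: 0.10 * Ing(mes), max: 0.15 * Ing(mes)}
  - {label: mes diet hnf+zsp share, expr: hnf-mes + zsp-mes, min: 0.15 * Ing(mes), max: 0.25 * Ing(mes)}
  - {label: mes diet mic share, expr: mic-mes, min: 0.40 * Ing(mes), max: 0.60 * Ing(mes)}
  - {label: mic diet bac+ph1 share, expr: bac-mic + ph1-mic, min: 0.10 * Ing(mic), max: 0.15 * Ing(mic)}
  - {label: mic diet ph2 share, expr: ph2-mic, min: 0.20 * Ing(mic), max: 0.30 * Ing(mic)}
  - {label: mic diet hnf+zsp share, expr: hnf-mic + zsp-mic, min: 0.40 * Ing(mic), max: 0.60 * Ing(mic)}
  - {label: hnf diet bac floor, expr: bac-hnf, min: 0.60 * Ing(hnf)}
  - {label: hnf diet ph1 floor, expr: ph1-hnf, min: 0.20 * Ing(hnf)}
  - {label: hnf detritus production cap, expr: hnf-det, max: 0.20 * Ing(hnf)}
  - {label: mes detritus production cap, expr: mes-det, max: 0.20 * Ing(mes)}
  - {label: attached-bacteria detritus share of bacterial production, expr: bac-det, min: 0.012 * BP, max: 0.056 * BP}
  - {label: ph3 share of total detritus production, expr: ph3-det, min: 0.16 * Det_total, max: 0.95 * Det_total}
  - {label: sporangia detritus production cap, expr: spg-det, max: 0.05 * ph3-spg}
  - {label: mes detritivory cap vs detritus production, expr: det-mes, max: 0.40 * Det_total}
  - {label: detritus dissolution cap vs net production, expr: det-doc, max: 0.10 * NPP}
  - {label: zoospore grazing mic vs mes ratio, expr: zsp-mic, min: 2 * zsp-mes}
  - {label: parasitism floor vs ph3 net production, expr: ph3-spg, min: 0.08 * NPP(ph3)}
  - {label: zoospore emission vs zoospore biomass, expr: spg-zsp, min: Biom(zsp)}
  - {label: ph3 share of total sinking, expr: ph3-los, min: 0.28 * Los_total}
  - {label: ph3 sinking floor, expr: ph3-los, min: '0.2'}
  - {label: mes share of total sinking, expr: mes-los, min: 0.45 * Los_total, max: 0.65 * Los_total}
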