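# Manifest of the eight published base clocks used by the ensemble models.
# Coefficient lists are not redistributed with this package; place each
# file (two-column CpG,Weight CSV with an Intercept row; for external-kind
# entries a one-CpG-per-line list) in the registry clock_dir, obtained from
# the cited original supplement. Entries may carry url/sha256 fields for
# automated fetching once a mirror is configured.
clocks:
  - name: AltumAge
    expected_n_cpgs: 20318
    transform: identity
    kind: external            # deep neural network; CpG list only
    filename: AltumAge.cpgs.txt
    source: "de Lima Camillo et al. 2022, npj Aging (pan-tissue DNN clock)"
  - name: Han2020
    expected_n_cpgs: 65
    transform: identity
    kind: linear
    filename: Han2020.csv
    source: "Han et al. 2020, Aging (pyrosequencing-selected blood CpGs)"
  - name: Hannum
    expected_n_cpgs: 71
    transform: identity
    kind: linear
    filename: Hannum.csv
    source: "Hannum et al. 2013, Mol Cell (HM450K whole blood)"
  - name: Horvath
    expected_n_cpgs: 353
    transform: horvath_log_linear
    kind: linear
    filename: Horvath.csv
    source: "Horvath 2013, Genome Biol (pan-tissue; log/linear anti-transform)"
  - name: SkinBlood
    expected_n_cpgs: 391
    transform: identity
    kind: linear
    filename: SkinBlood.csv
    source: "Horvath et al. 2018, Aging (skin & blood clock)"
  - name: PhenoAge
    expected_n_cpgs: 513
    transform: identity
    kind: linear
    filename: PhenoAge.csv
    source: "Levine et al. 2018, Aging (DNAm PhenoAge)"
  - name: YingCausAge
    expected_n_cpgs: 586
    transform: identity
    kind: linear
    filename: YingCausAge.csv
    source: "Ying et al. 2024, Nat Aging (causality-enriched CpGs)"
  - name: Zhang2019
    expected_n_cpgs: 514
    transform: identity
    kind: linear
    filename: Zhang2019.csv
    source: "Zhang et al. 2019, Genome Med (blood & saliva elastic net)"
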