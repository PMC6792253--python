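# Reference feature spec set: 95 encoded columns.
#
# The names mirror the annotation labels a clinical annotation engine exposes
# (deleteriousness, conservation, population counts, curated-database bins,
# splice and protein-effect predictors, transcript effect categories), padded
# with documented generic numeric/categorical slots.  The exact annotation
# inventory of any given annotation engine differs by deployment, so this
# file is configuration, not a constant: pass your own spec file to
# `varprior featurize --specs` to match your annotation source.
#
# Numeric defaults sit OUTSIDE the expected range on the less-impactful side
# (e.g. a missing conservation score errs toward "not conserved"); allele
# frequencies / population counts default to 0.0 (absent from the database
# means never observed).

# --- phenotype scores (computed by the phenoscore stage) -------------------
- {name: HPO-cosine, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 1.0]}
- {name: PyxisMap, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 1.0]}

# --- variant-level deleteriousness and conservation ------------------------
- {name: CADD Scaled, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 99.0]}
- {name: phylop100 conservation, kind: numeric_single, default_value: -25.0, expected_range: [-20.0, 10.0]}
- {name: phylop conservation, kind: numeric_single, default_value: -25.0, expected_range: [-20.0, 10.0]}
- {name: phastcon100 conservation, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 1.0]}
- {name: phastcon conservation, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 1.0]}
- {name: GERP rsScore, kind: numeric_single, default_value: -15.0, expected_range: [-12.3, 6.17]}
- {name: GERP element score, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 1000.0]}

# --- splice predictors -----------------------------------------------------
- {name: ADA Boost Splice Prediction, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 1.0]}
- {name: Random Forest Splice Prediction, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 1.0]}
- {name: Splice site distance, kind: numeric_single, default_value: 2000000.0, expected_range: [0.0, 1000000.0]}

# --- population counts and frequencies (absent == never observed) ----------
- {name: Gnomad Genome total allele count, kind: numeric_single, is_allele_freq: true}
- {name: Gnomad Exome total allele count, kind: numeric_single, is_allele_freq: true}
- {name: Gnomad Genome allele frequency, kind: numeric_single, is_allele_freq: true}
- {name: Gnomad Exome allele frequency, kind: numeric_single, is_allele_freq: true}
- {name: Gnomad Genome homozygous count, kind: numeric_single, is_allele_freq: true}

# --- gene-level scores -----------------------------------------------------
- {name: Haploinsufficiency score, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 1.0]}
- {name: Gene intolerance percentile, kind: numeric_single, default_value: 101.0, expected_range: [0.0, 100.0]}
- {name: Missense Z-score, kind: numeric_single, default_value: -10.0, expected_range: [-8.0, 12.0]}
- {name: pLI score, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 1.0]}
- {name: CCR percentile, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 100.0]}
- {name: LoFtool percentile, kind: numeric_single, default_value: 101.0, expected_range: [0.0, 100.0]}
- {name: Gene damage index, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 30.0]}
- {name: S-het score, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 1.0]}

# --- region context --------------------------------------------------------
- {name: Regulatory element score, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 1.0]}
- {name: Segmental duplication fraction, kind: numeric_single, default_value: 2.0, expected_range: [0.0, 1.0]}
- {name: Repeat overlap fraction, kind: numeric_single, default_value: 2.0, expected_range: [0.0, 1.0]}
- {name: Mappability score, kind: numeric_single, default_value: 2.0, expected_range: [0.0, 1.0]}
- {name: Distance to gene boundary, kind: numeric_single, default_value: 2000000.0, expected_range: [0.0, 1000000.0]}
- {name: Transcript percentile, kind: numeric_single, default_value: -1.0, expected_range: [0.0, 100.0]}

# --- multi-value numerics (one value per transcript; reduced to the worst) -
- {name: SIFT score, kind: numeric_multi, worst_direction: min, default_value: 2.0, expected_range: [0.0, 1.0]}
- {name: PolyPhen HV score, kind: numeric_multi, worst_direction: max, default_value: -1.0, expected_range: [0.0, 1.0]}
- {name: PolyPhen HD score, kind: numeric_multi, worst_direction: max, default_value: -1.0, expected_range: [0.0, 1.0]}
- {name: Meta SVM score, kind: numeric_multi, worst_direction: max, default_value: -3.0, expected_range: [-2.0, 3.0]}
- {name: Exon distance, kind: numeric_multi, worst_direction: min, default_value: 2000000.0, expected_range: [0.0, 1000000.0]}

# --- curated-database and predictor categories (bin-count encoded) ---------
- name: HGMD assessment type
  kind: categorical
  vocabulary: [DM, "DM?", DP, DFP, FP]
- name: HGMD association confidence
  kind: categorical
  vocabulary: [High, Medium, Low]
- name: ClinVar Classification
  kind: categorical
  vocabulary: [Pathogenic, Likely Pathogenic, Uncertain Significance, Likely Benign, Benign]
- name: Meta Svm Prediction
  kind: categorical
  vocabulary: [D, T]
- name: PolyPhen HV Prediction
  kind: categorical
  vocabulary: [D, P, B]
- name: PolyPhen HD Prediction
  kind: categorical
  vocabulary: [D, P, B]
- name: SIFT Prediction
  kind: categorical
  vocabulary: [D, T]
- name: Effects
  kind: categorical
  vocabulary: [Premature stop, Possible splicing modifier, Missense, Synonymous,
               Frameshift, In-frame indel, Canonical splice site, Intronic, UTR]
- name: Gene disease association source
  kind: categorical
  vocabulary: [OMIM, Orphanet, HGMD, ClinVar]
- name: Inheritance mode
  kind: categorical
  vocabulary: [AD, AR, XL, MT]
- name: Variant impact
  kind: categorical
  vocabulary: [HIGH, MODERATE, LOW, MODIFIER]
- name: Zygosity
  kind: categorical
  vocabulary: [het, hom, hemi]
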