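"""Synthetic reconstruction of a six-disease polygenic-score parameter set.

This file holds the inputs for the packaged six-disease worked example:
per-disease discrimination (AUC of the fitted genome-wide polygenic risk
score), lifetime prevalence, SNP heritability (the ceiling on the liability
variance a genotype-based score can explain), and the matrix of genetic
correlations used both for the liability correlations Sigma_L and for the
correlation structure of the scores.

SYNTHETIC / RECONSTRUCTED: the original worked example's parameter tables
were not available to this package, so the values below were assembled once
from the public 2018-2019 genome-wide PRS and LD-score-regression literature
(PGC schizophrenia and bipolar GWAS, Mavaddat et al. breast cancer,
CAD and type-2 diabetes meta-analysis scores, IBD/Crohn's GWAS, LD-Hub
genetic correlations).  They are realistic for that era but are a stand-in,
not a transcription; results computed from them should be read as "a
six-disease PRS panel of this kind", not as a reproduction of any specific
published table.
"""

DISEASES = (
    "bipolar_disorder",
    "breast_cancer",
    "coronary_artery_disease",
    "crohns_disease",
    "schizophrenia",
    "type_2_diabetes",
)

#: AUC of the fitted genome-wide PRS (score alone, no covariates)
AUC = (0.65, 0.63, 0.63, 0.64, 0.72, 0.66)

#: lifetime prevalence used to set the liability thresholds
PREVALENCE = (0.01, 0.12, 0.06, 0.005, 0.01, 0.08)

#: SNP heritability on the liability scale (upper bound for liability R^2)
SNP_H2 = (0.25, 0.13, 0.13, 0.25, 0.26, 0.17)

#: genetic correlations (LD-score-regression era estimates), order as DISEASES
GENETIC_CORRELATION = (
    (1.00, 0.02, 0.02, 0.05, 0.68, 0.03),
    (0.02, 1.00, 0.01, 0.00, 0.02, 0.07),
    (0.02, 0.01, 1.00, 0.02, 0.00, 0.39),
    (0.05, 0.00, 0.02, 1.00, 0.08, 0.02),
    (0.68, 0.02, 0.00, 0.08, 1.00, 0.03),
    (0.03, 0.07, 0.39, 0.02, 0.03, 1.00),
)
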