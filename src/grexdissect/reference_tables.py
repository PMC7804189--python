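"""Published worked-example tables for the threshold-counting utilities.

Two reference tables from a blood case/control depression cohort analysis of
type-I interferon (IFN alpha/beta) signalling: per-gene permutation p-values
for observed differential expression (oDEG), for the environmentally
regulated component (EReX) and for the genetically regulated component
(GReX), together with each gene's rank among all tested genes when ordered
by the observed-expression association.

These are inputs for worked examples and regression tests of the counting
and enrichment utilities — they are data, not outputs of this package.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = [
    "ifn_pathway_odegs",
    "grex_significant_odegs",
    "UNIVERSE_SIZE",
    "IFN_GENES_IN_UNIVERSE",
]

# genes in the analysis universe (all genes with predicted expression that
# passed the cohort's read-support filter) and IFN pathway members among them
UNIVERSE_SIZE = 5359
IFN_GENES_IN_UNIVERSE = 24

# IFN alpha/beta signalling genes that were observed DEGs, with permutation
# p-values per component and the oDEG rank
_IFN_ODEGS = """\
gene	odeg_p	erex_p	grex_p	odeg_rank
OAS1	1.25e-04	1.25e-04	6.76e-01	1
MX1	2.50e-04	2.37e-03	1.50e-02	2
ADAR	5.00e-04	3.75e-04	5.97e-01	7
IRF7	1.12e-03	1.50e-03	2.74e-02	16
ISG15	1.62e-03	1.62e-03	4.89e-01	20
IFIT1	2.00e-03	1.87e-03	8.29e-02	21
IFI35	6.88e-03	1.24e-02	1.10e-01	62
MX2	1.05e-02	1.01e-02	4.92e-01	88
OASL	1.25e-02	2.95e-02	1.54e-01	104
IFNAR2	3.84e-02	2.76e-02	9.12e-01	292
"""

# the 39 oDEGs whose GReX component reached nominal significance, with the
# matching EReX p-values and oDEG ranks
_GREX_SIG_ODEGS = """\
gene	odeg_p	grex_p	erex_p	odeg_rank
MX1	2.50e-04	1.50e-02	2.38e-03	2
TNFRSF10B	5.00e-04	8.38e-03	1.93e-02	3
RABEPK	5.00e-04	1.11e-02	7.13e-03	4
SDK1	7.50e-04	6.25e-04	2.93e-02	10
IRF7	1.13e-03	2.74e-02	1.50e-03	16
RBM6	2.25e-03	3.01e-02	1.96e-02	25
ZNF584	3.88e-03	4.04e-02	5.61e-02	35
EPOR	4.25e-03	4.33e-02	1.46e-02	39
SCO2	6.00e-03	1.88e-03	2.58e-01	52
SGSH	8.00e-03	2.64e-02	8.99e-02	67
TSGA10	9.00e-03	3.04e-02	1.25e-01	74
XAB2	9.13e-03	2.81e-02	5.85e-02	78
ZNF514	1.05e-02	1.00e-03	3.90e-01	87
PSMA4	1.14e-02	4.06e-02	9.06e-02	93
PLCH2	1.14e-02	4.73e-02	7.58e-02	94
TMEM97	1.21e-02	8.75e-03	3.02e-01	99
CYP2D6	1.21e-02	1.45e-02	2.57e-01	100
AHSA2	1.29e-02	2.20e-02	2.10e-01	105
ATPAF2	1.40e-02	3.50e-03	1.17e-01	113
ODF3B	1.50e-02	2.50e-03	1.65e-01	121
ZNF132	1.58e-02	3.14e-02	3.43e-01	127
BLM	1.68e-02	1.74e-02	3.35e-01	134
EPS15L1	1.89e-02	2.15e-02	4.36e-02	153
TMEM121	1.99e-02	3.46e-02	2.43e-01	159
UAP1L1	2.04e-02	2.81e-02	3.22e-01	165
PEX5	2.14e-02	3.26e-02	3.40e-01	171
DNAJC18	2.40e-02	5.50e-03	3.64e-01	193
IGSF8	2.44e-02	1.31e-02	9.94e-02	195
ZNF354A	2.58e-02	3.01e-02	2.35e-01	202
GFRA2	2.91e-02	1.88e-03	7.00e-01	224
SLIT1	3.00e-02	2.09e-02	4.64e-01	233
ZNF83	3.16e-02	2.88e-03	4.62e-01	246
MAN1A1	3.43e-02	3.96e-04	2.79e-01	261
CTNNA1	3.65e-02	2.15e-02	4.71e-01	278
ANXA6	3.81e-02	1.50e-03	8.33e-01	290
HOXA4	3.95e-02	3.93e-02	8.81e-02	296
DNASE2	4.56e-02	2.06e-02	6.34e-01	327
KIR2DL4	4.59e-02	1.09e-02	5.08e-02	328
TERF2	4.99e-02	2.85e-02	3.20e-02	352
"""


def ifn_pathway_odegs() -> pd.DataFrame:
    """IFN alpha/beta pathway oDEGs with per-component permutation p-values."""
    return pd.read_csv(StringIO(_IFN_ODEGS), sep="\t")


def grex_significant_odegs() -> pd.DataFrame:
    """The 39 oDEGs with nominally significant GReX association."""
    return pd.read_csv(StringIO(_GREX_SIG_ODEGS), sep="\t")
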