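"""Published summary statistics used as worked-example inputs.

The original prospective study of neonatal methylation and adolescent
substance use (ALSPAC subsample, n = 244, Illumina 450k, 413,510 post-QC
probes) reported 65 discovery DMPs with their standardized effects and raw
p-values, plus the fit statistics of the substance-use factor model. The
raw individual-level data are access-controlled, but these printed summary
numbers are enough to recompute two quantities end to end: the BH q-value
of the top probe within the full 413,510-test family, and the RMSEA implied
by the printed chi-square, degrees of freedom and sample size.
"""

from __future__ import annotations

import pandas as pd

# Reported sample size and post-QC probe count of the discovery EWAS.
DISCOVERY_N = 244
DISCOVERY_M_PROBES = 413_510

# Reported substance-use factor model fit (chi-square, df, N).
FACTOR_FIT_CHI2 = 49.55
FACTOR_FIT_DF = 18
FACTOR_FIT_N = DISCOVERY_N

# (probe, gene, chromosome, genomic feature, position, Std B, p) of the 65
# discovery DMPs, ordered by p.
_DISCOVERY_ROWS = [
    ("cg04941418", "PACSIN1", "6", "5'UTR", 34493129, -0.34, 1.10e-08),
    ("cg11074746", "MEMO1", "2", "TSS1500", 32236343, 0.31, 1.77e-07),
    ("cg00335219", "", "16", "", 86012305, 0.27, 1.79e-07),
    ("cg07395930", "CLSTN1", "1", "Body", 9791419, -0.31, 3.84e-07),
    ("cg01589998", "FOXN4", "12", "Body", 109729478, 0.31, 3.92e-07),
    ("cg13978601", "PPP2R4", "9", "Body", 131905041, -0.31, 4.10e-07),
    ("cg23361356", "SLC9A3", "5", "Body", 508834, -0.31, 4.17e-07),
    ("cg27020216", "SGEF", "3", "Body", 153840347, 0.29, 8.35e-07),
    ("cg14632140", "LMO3", "12", "5'UTR", 16758112, 0.29, 9.82e-07),
    ("cg08080985", "C9orf95", "9", "Body", 77703079, 0.30, 1.07e-06),
    ("cg20685020", "ATP6V0B", "1", "5'UTR", 44440676, 0.30, 1.34e-06),
    ("cg25229198", "ADAMTS6", "5", "Body", 64660684, -0.30, 1.38e-06),
    ("cg05968179", "USP6NL", "10", "Body", 11505706, -0.29, 1.42e-06),
    ("cg01009697", "NTRK2", "9", "TSS1500", 87283470, 0.29, 1.56e-06),
    ("cg19026817", "", "20", "", 56782259, -0.29, 1.64e-06),
    ("cg05116255", "ANKRD30A", "10", "TSS1500", 37413782, -0.29, 1.85e-06),
    ("cg04799664", "NLRC5", "16", "5'UTR", 57053850, -0.29, 1.85e-06),
    ("cg07746699", "IFT140", "16", "TSS200", 1662305, 0.30, 1.87e-06),
    ("cg02290110", "SHC2", "19", "TSS1500", 461808, 0.29, 1.91e-06),
    ("cg06951646", "TRRAP", "7", "Body", 98586548, -0.29, 1.92e-06),
    ("cg02052845", "HGS", "17", "Body", 79658835, -0.29, 2.00e-06),
    ("cg05033322", "ATM", "11", "TSS1500", 108093245, 0.29, 2.08e-06),
    ("cg02404636", "SFI1", "22", "TSS1500", 31891804, 0.29, 2.10e-06),
    ("cg05620865", "AP3B1", "5", "Body", 77588408, -0.29, 2.22e-06),
    ("cg14291256", "MMP21", "10", "Body", 127461065, -0.29, 2.25e-06),
    ("cg12593849", "STX12", "1", "3'UTR", 28150710, -0.29, 2.31e-06),
    ("cg10844884", "ZNF22", "10", "Body", 45498904, -0.29, 2.32e-06),
    ("cg27242945", "CAV1", "7", "1st exon", 116165134, 0.28, 2.35e-06),
    ("cg13562386", "TAGLN2", "1", "TSS1500", 159895724, 0.29, 2.36e-06),
    ("cg25767859", "PKD1L1", "7", "Body", 47859324, -0.29, 2.37e-06),
    ("cg12202228", "FNDC3B", "3", "Body", 171871829, -0.29, 2.52e-06),
    ("cg20056324", "NEUROD4", "12", "TSS200", 55413610, 0.29, 2.60e-06),
    ("cg27122536", "FOXF1", "16", "1st exon", 86544658, 0.29, 2.67e-06),
    ("cg14661886", "PRRT3", "3", "TSS200", 9994197, 0.29, 2.75e-06),
    ("cg27596068", "SERPINH1", "11", "TSS1500", 75272301, -0.28, 2.77e-06),
    ("cg23088142", "", "3", "", 137531265, 0.29, 2.99e-06),
    ("cg08625693", "DLG3", "X", "Body", 69674126, -0.26, 3.09e-06),
    ("cg05463325", "RAB4A", "1", "TSS1500", 229406534, 0.29, 3.23e-06),
    ("cg01894322", "PPP1R1B", "17", "Body", 37789575, -0.28, 3.38e-06),
    ("cg13138952", "RPH3AL", "17", "Body", 236013, -0.29, 3.39e-06),
    ("cg01338630", "RASD2", "22", "3'UTR", 35948166, -0.27, 3.77e-06),
    ("cg22409100", "SLC8A1", "2", "TSS1500", 40658918, 0.14, 4.01e-06),
    ("cg24954684", "CLIP1", "12", "TSS1500", 122907641, 0.27, 4.08e-06),
    ("cg22467567", "IGFBP5", "2", "5'UTR", 217559885, 0.28, 4.39e-06),
    ("cg25179876", "NRP1", "10", "Body", 33483109, -0.19, 4.47e-06),
    ("cg04388666", "CCDC85C", "14", "TSS1500", 100072073, 0.28, 4.61e-06),
    ("cg13244417", "TMTC4", "13", "TSS200", 101327186, 0.28, 4.75e-06),
    ("cg16661000", "HAPLN3", "15", "5'UTR", 89437710, 0.27, 4.81e-06),
    ("cg00276455", "", "6", "", 54904638, -0.28, 4.82e-06),
    ("cg08261702", "LOC728743", "7", "Body", 150103112, 0.25, 5.02e-06),
    ("cg05168344", "LZTR1", "22", "Body", 21340160, -0.28, 5.07e-06),
    ("cg02725795", "FAM175A", "4", "Body", 84405871, 0.27, 5.18e-06),
    ("cg20336014", "MGEA5", "10", "TSS200", 103578255, 0.27, 5.49e-06),
    ("cg26047334", "TNS1", "2", "5'UTR", 218785909, 0.25, 5.56e-06),
    ("cg18769584", "LZTFL1", "3", "3'UTR", 45866619, -0.27, 5.64e-06),
    ("cg13083436", "LUZP2", "11", "TSS200", 24518414, 0.28, 5.74e-06),
    ("cg23530543", "HEPN1", "11", "TSS1500", 124788414, -0.28, 5.98e-06),
    ("cg02957771", "FBXO31", "16", "Body", 87380349, -0.27, 6.13e-06),
    ("cg17396676", "EPS15L1", "19", "TSS1500", 16583990, -0.28, 6.56e-06),
    ("cg09278687", "TBX6", "16", "Body", 30100430, -0.28, 6.91e-06),
    ("cg20643362", "C19orf12", "19", "1st exon", 30206369, 0.27, 7.37e-06),
    ("cg10395806", "CTTN", "11", "Body", 70280601, -0.28, 7.43e-06),
    ("cg00877150", "BCOR", "X", "5'UTR", 39972039, -0.27, 7.52e-06),
    ("cg20319698", "LRRFIP1", "2", "Body", 238644099, -0.27, 7.73e-06),
    ("cg14712611", "ANK2", "4", "5'UTR", 113739379, 0.27, 7.74e-06),
]


def discovery_table() -> pd.DataFrame:
    """The 65 published discovery DMPs as a DataFrame (index = probe id)."""
    df = pd.DataFrame(
        _DISCOVERY_ROWS,
        columns=["probe_id", "gene", "chrom", "feature", "pos", "std_beta", "p"])
    return df.set_index("probe_id")
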