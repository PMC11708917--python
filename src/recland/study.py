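"""Published barn owl linkage-map summary statistics.

These are the headline numbers of the barn owl pedigree map (350 meioses,
40 linkage groups over 1,196.47 Mb of assembly) used as inputs to
worked-example derivations: crossovers per meiosis and genome-average
recombination rates.
"""

MALE_COS = 3_972
FEMALE_COS = 4_250
N_MEIOSES = 350

AUTOSOMAL_MAP_CM = 2_580.0  # sex-averaged, 39 autosomal LGs
ASSEMBLY_SPAN_MB = 1_196.47  # all 40 LGs
Z_LENGTH_MB = 90.3
MALE_Z_CM = 69.28


def cos_per_meiosis() -> float:
    """Average observed crossovers per meiosis across both sexes."""
    return (MALE_COS + FEMALE_COS) / N_MEIOSES


def autosomal_mean_rate_cm_per_mb() -> float:
    """Genome-average autosomal rate: map length over autosomal span."""
    return AUTOSOMAL_MAP_CM / (ASSEMBLY_SPAN_MB - Z_LENGTH_MB)


def z_male_rate_cm_per_mb() -> float:
    """Male recombination rate on the Z chromosome."""
    return MALE_Z_CM / Z_LENGTH_MB
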