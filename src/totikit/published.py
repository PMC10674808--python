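"""Published reference values for the two Geotrichum candidum totiviruses.

These constants reproduce numbers printed in the public descriptions of
GcTV2-Gc6 (GenBank OR250782) and GcTV4-Gc6 (GenBank OR250783): genome
layout coordinates, frameshift-element coordinates, and the per-length
small-RNA read counts for the viral and host (G. candidum LMA-244_clib)
libraries.  They are used as default parameterizations for the synthetic
generator and as fixtures for consistency checks; nothing in the analysis
code depends on them.
"""

from __future__ import annotations

# Genome layouts, 1-based inclusive coordinates.
GCTV2_LAYOUT = {
    "genome_id": "GcTV2-Gc6",
    "genome_length": 4592,
    "gc_percent": 45.5,
    "utr5_len": 29,
    "orf1_start": 30,
    "orf1_end": 2072,
    "orf1_frame": 3,
    "ir_len": 326,
    "orf2_start": 2399,
    "orf2_end": 4555,
    "orf2_frame": 2,
    "utr3_len": 37,
    "slippery_heptamer": "GGGUUUA",
    "slippery_start": 1958,
    "slippery_end": 1964,
    "spacer_len": 4,
    "pk_start": 1969,
    "pk_end": 2023,
    "fusion_len_aa": 1508,
    "orf1_nt_len": 2043,
    "orf1_aa_len": 680,
    "orf1_mass_kda": 76.6,
    "orf2_nt_len": 2157,
    "orf2_aa_len": 718,
    "orf2_mass_kda": 82.06,
}

GCTV4_LAYOUT = {
    "genome_id": "GcTV4-Gc6",
    "genome_length": 4530,
    "gc_percent": 42.6,
    "utr5_len": 5,
    "orf1_start": 6,
    "orf1_end": 2102,
    "orf1_frame": 3,
    "ir_len": 20,
    "orf2_start": 2123,
    "orf2_end": 4495,
    "orf2_frame": 2,
    "utr3_len": 35,
    "slippery_heptamer": "UUUUUUA",
    "slippery_start": 1943,
    "slippery_end": 1949,
    "spacer_len": 27,
    "pk_start": 1977,
    "pk_end": 1997,
    "fusion_len_aa": 1496,
    "orf1_nt_len": 2097,
    "orf1_aa_len": 698,
    "orf1_mass_kda": 78.6,
    "orf2_nt_len": 2373,
    "orf2_aa_len": 790,
    "orf2_mass_kda": 90.11,
}

# Per-length read counts of the small-RNA libraries mapped with <=1
# mismatch, as printed: {length: (total, perfect_match, one_mismatch)}.
# Lengths with no detected reads are 0.
SRNA_COUNTS_GCTV2 = {
    10: (56987, 1450, 55537),
    11: (15616, 522, 15094),
    12: (7309, 99, 7210),
    13: (12614, 21, 12593),
    14: (615, 5, 610),
    15: (369, 0, 369),
    16: (47, 0, 47),
    17: (133, 0, 133),
    18: (337, 0, 337),
    19: (7, 0, 7),
    20: (10, 0, 10),
}

SRNA_COUNTS_GCTV4 = {
    10: (75858, 545, 75313),
    11: (26851, 232, 26619),
    12: (4859, 43, 4816),
    13: (2410, 8, 2402),
    14: (695, 8, 687),
    15: (386, 5, 381),
    16: (154, 0, 154),
    17: (43, 0, 43),
    18: (49, 0, 49),
    19: (30, 0, 30),
}

SRNA_COUNTS_HOST = {
    10: (579036, 579020, 16),
    11: (439532, 436820, 2712),
    12: (980610, 866277, 114333),
    13: (1247012, 646920, 600092),
    14: (2423441, 257021, 2166420),
    15: (2374600, 243264, 2131336),
    16: (1670491, 262674, 1407817),
    17: (3120220, 301826, 2818394),
    18: (1246059, 337262, 908797),
    19: (2103211, 602221, 1500990),
    20: (12694084, 1312581, 11381503),
    21: (1503777, 535043, 968734),
    22: (1025590, 351560, 674030),
    23: (1181768, 269011, 912757),
    24: (1518337, 233035, 1285302),
    25: (240986, 121743, 119243),
    26: (151291, 79791, 71500),
    27: (109991, 64998, 44993),
    28: (87651, 51255, 36396),
    29: (49420, 23245, 26175),
    30: (39603, 19653, 19950),
    ">30": (77785, 35462, 42323),
}

# Library-level totals as printed.
SRNA_TOTALS = {
    "GcTV2-Gc6": (94044, 2097, 91947),
    "GcTV4-Gc6": (111335, 841, 110494),
    "host": (34864495, 7630682, 27233813),
}
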