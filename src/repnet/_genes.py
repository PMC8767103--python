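"""Static pools of human immunoglobulin germline gene names.

Gene-level identifiers (no allele suffixes) for the heavy (IGH), kappa (IGK)
and lambda (IGL) loci, used by the synthetic cohort generator so that its
output carries nomenclature-realistic V/J assignments. The lists are not
exhaustive; they cover the commonly expressed functional genes.
"""

IGHV_GENES = (
    "IGHV1-2", "IGHV1-3", "IGHV1-8", "IGHV1-18", "IGHV1-24", "IGHV1-46",
    "IGHV1-69", "IGHV2-5", "IGHV2-26", "IGHV2-70", "IGHV3-7", "IGHV3-9",
    "IGHV3-11", "IGHV3-15", "IGHV3-20", "IGHV3-21", "IGHV3-23", "IGHV3-30",
    "IGHV3-33", "IGHV3-43", "IGHV3-48", "IGHV3-49", "IGHV3-53", "IGHV3-66",
    "IGHV3-74", "IGHV4-4", "IGHV4-31", "IGHV4-34", "IGHV4-39", "IGHV4-59",
    "IGHV4-61", "IGHV5-51", "IGHV6-1", "IGHV7-4-1",
)

IGKV_GENES = (
    "IGKV1-5", "IGKV1-6", "IGKV1-8", "IGKV1-9", "IGKV1-12", "IGKV1-16",
    "IGKV1-17", "IGKV1-27", "IGKV1-33", "IGKV1-39", "IGKV2-24", "IGKV2-28",
    "IGKV2-30", "IGKV3-11", "IGKV3-15", "IGKV3-20", "IGKV4-1", "IGKV5-2",
    "IGKV6-21", "IGKV1D-13",
)

IGLV_GENES = (
    "IGLV1-36", "IGLV1-40", "IGLV1-44", "IGLV1-47", "IGLV1-51", "IGLV2-8",
    "IGLV2-11", "IGLV2-14", "IGLV2-23", "IGLV3-1", "IGLV3-10", "IGLV3-19",
    "IGLV3-21", "IGLV3-25", "IGLV4-69", "IGLV5-45", "IGLV6-57", "IGLV7-43",
    "IGLV7-46", "IGLV8-61",
)

IGHJ_GENES = ("IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6")
IGKJ_GENES = ("IGKJ1", "IGKJ2", "IGKJ3", "IGKJ4", "IGKJ5")
IGLJ_GENES = ("IGLJ1", "IGLJ2", "IGLJ3", "IGLJ6", "IGLJ7")

V_POOLS = {"IGH": IGHV_GENES, "IGK": IGKV_GENES, "IGL": IGLV_GENES}
J_POOLS = {"IGH": IGHJ_GENES, "IGK": IGKJ_GENES, "IGL": IGLJ_GENES}
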