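"""Packaged HLA gene regions (NCBI Build 37, chromosome 6).

These spans already include the 100 kb up/downstream buffer around each
locus (the class II loci merge the A1/B1 gene pairs), so they are used
directly; :func:`popdiff.catalog.extend_region` is for raw, unbuffered gene
coordinates supplied by the user.
"""

from __future__ import annotations

from .core import GeneRegion

HLA_REGIONS: tuple[GeneRegion, ...] = (
    GeneRegion("HLA-A", "6", 29_810_247, 30_013_868),
    GeneRegion("HLA-B", "6", 31_221_649, 31_424_989),
    GeneRegion("HLA-C", "6", 31_136_526, 31_339_913),
    GeneRegion("HLA-DR", "6", 32_307_619, 32_657_613),
    GeneRegion("HLA-DQ", "6", 32_505_183, 32_734_466),
    GeneRegion("HLA-DP", "6", 32_932_346, 33_153_681),
)

# conventional major-haplotype frequency thresholds per locus
MAJOR_THRESHOLDS: dict[str, float] = {
    "HLA-A": 0.10, "HLA-B": 0.10, "HLA-C": 0.10,
    "HLA-DR": 0.10, "HLA-DQ": 0.06, "HLA-DP": 0.06,
}
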