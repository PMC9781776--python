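"""Analysis thresholds shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["AnalysisConfig", "CONDITIONS", "PATHWAY_COGNATES"]

#: Canonical nine-monosaccharide growth-condition vocabulary.
CONDITIONS: tuple[str, ...] = (
    "D-glucose",
    "D-fructose",
    "D-galactose",
    "D-mannose",
    "L-rhamnose",
    "D-xylose",
    "L-arabinose",
    "D-galacturonic acid",
    "D-glucuronic acid",
)

#: Sugar-specific pathways and the growth condition that induces their genes.
#: Central-carbon pathways (glycolysis, TCA, glyoxylate, PPP, glycerol) have no
#: single inducing sugar and are deliberately absent.
PATHWAY_COGNATES: dict[str, str] = {
    "pcp": "D-xylose",
    "l_rhamnose": "L-rhamnose",
    "d_galacturonic_acid": "D-galacturonic acid",
    "d_galactose": "D-galactose",
    "leloir": "D-galactose",
    "galox": "D-galactose",
    "dld": "D-galactose",
    "d_mannose": "D-mannose",
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the multi-omics screens.

    fpkm_threshold
        Pseudogene filter: candidates with maximum FPKM below this value in
        every tested condition are demoted.
    pcc_min / alpha
        Gene-metabolite correlation screen: |PCC| >= pcc_min and p < alpha.
    pcc_strong
        Strong correlations are positive with PCC >= pcc_strong.
    induction_fold
        A gene counts as sugar-induced when its cognate-condition FPKM is the
        row maximum and at least this fold over the median of the other
        conditions.
    detection_fraction
        Proteins detected in fewer than this fraction of conditions are
        dropped from pathway abundance profiles.
    """

    fpkm_threshold: float = 10.0
    pcc_min: float = 0.5
    alpha: float = 0.05
    pcc_strong: float = 0.8
    induction_fold: float = 2.0
    detection_fraction: float = 1.0 / 3.0
    linkage: str = "average"
    distance: str = "pearson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fpkm_threshold < 0:
            raise ValueError("fpkm_threshold must be non-negative")
        if not 0 <= self.pcc_min <= 1 or not 0 <= self.pcc_strong <= 1:
            raise ValueError("correlation thresholds must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.induction_fold < 1:
            raise ValueError("induction_fold must be >= 1")
        if not 0 < self.detection_fraction <= 1:
            raise ValueError("detection_fraction must lie in (0, 1]")
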