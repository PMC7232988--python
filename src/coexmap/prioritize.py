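"""SD-closeness prioritization: keep the decile of screened genes whose map
standard deviation is nearest the target map's SD.

The map SD measures how spread a gene's predicted expression is across the
analysis sites; a gene whose distribution resembles the target's (e.g. a
receptor's binding-potential map) is ranked ahead of genes that merely
correlate.  "90th percentile" means the top 10% by closeness
|SD_gene - SD_target|; the alternative reading (genes with SD above the
90th percentile of SDs) is available via ``strategy``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from coexmap.errors import ConfigurationError
from coexmap.screen import GeneRecord

VALID_SD_DEFINITIONS = ("sample", "population")
VALID_STRATEGIES = ("closeness", "high_sd")


@dataclass
class PrioritizationConfig:
    """Percentile and SD conventions of the prioritization step.

    ``percentile=90`` keeps genes at or above the 90th percentile of
    SD-closeness, i.e. the 10% of screened genes whose SD is nearest the
    target's.  ``sd_definition`` selects the n-1 (sample, default) or n
    (population) divisor.
    """

    percentile: float = 90.0
    sd_definition: str = "sample"
    strategy: str = "closeness"

    def __post_init__(self):
        if not 0.0 < self.percentile < 100.0:
            raise ConfigurationError(
                f"percentile must be in (0, 100); got {self.percentile}"
            )
        if self.sd_definition not in VALID_SD_DEFINITIONS:
            raise ConfigurationError(
                f"sd_definition must be one of {VALID_SD_DEFINITIONS}: "
                f"{self.sd_definition!r}"
            )
        if self.strategy not in VALID_STRATEGIES:
            raise ConfigurationError(
                f"strategy must be one of {VALID_STRATEGIES}: {self.strategy!r}"
            )


def map_sd(
    values: np.ndarray,
    mask: np.ndarray | None = None,
    sd_definition: str = "sample",
) -> float:
    """Standard deviation of a map over masked sites (n-1 divisor default)."""
    values = np.asarray(values, dtype=float)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise ValueError(f"need >= 2 masked sites for an SD, got {len(values)}")
    if sd_definition not in VALID_SD_DEFINITIONS:
        raise ConfigurationError(
            f"sd_definition must be one of {VALID_SD_DEFINITIONS}: {sd_definition!r}"
        )
    return float(np.std(values, ddof=1 if sd_definition == "sample" else 0))


def sd_percentile_selection(
    screened: list[GeneRecord],
    target_sd: float,
    config: PrioritizationConfig | None = None,
) -> list[GeneRecord]:
    """Keep the screened genes whose SD is closest to ``target_sd``.

    Closeness c(g) = |sd(g) - target_sd|; genes with c at or below the
    (100 - percentile)-th percentile of {c} are kept (linear interpolation
    between order statistics; ties at the cutoff all kept).  Output is
    sorted by sd descending, then gene_id ascending — the ordering of a
    results table ranked by distributional spread.

    With ``strategy="high_sd"`` the rule instead keeps genes whose SD is
    at or above the ``percentile``-th percentile of SDs.
    """
    config = config or PrioritizationConfig()
    if not screened:
        raise ValueError("screened gene list is empty")
    if not np.isfinite(target_sd) or target_sd < 0:
        raise ValueError(f"target_sd must be a nonnegative number; got {target_sd}")
    sds = np.array([g.sd for g in screened], dtype=float)
    if not np.all(np.isfinite(sds)):
        bad = [g.gene_id for g, s in zip(screened, sds) if not np.isfinite(s)]
        raise ValueError(f"screened genes without an SD: {bad[:5]}")
    if config.strategy == "closeness":
        closeness = np.abs(sds - target_sd)
        cutoff = np.percentile(closeness, 100.0 - config.percentile, method="linear")
        keep = closeness <= cutoff
    else:
        cutoff = np.percentile(sds, config.percentile, method="linear")
        keep = sds >= cutoff
    kept = [g for g, k in zip(screened, keep) if k]
    kept.sort(key=lambda g: (-g.sd, g.gene_id))
    return kept
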