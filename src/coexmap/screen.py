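"""Coexpression screen: rank-correlate predicted gene maps with the target
map and apply the two-threshold filter (Spearman rho vs target, LOOCV r).

Genes pass the default screen iff rho >= 0.7 (high coexpression with the
target map) and LOOCV r > 0.3 (prediction validity / signal-to-noise).
The screen works on effect size, not p-values, so no multiplicity
correction is applied here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from coexmap.errors import ConfigurationError


@dataclass
class GeneRecord:
    """Per-gene screen statistics (one row of the results table).

    ``rho_target``: Spearman rho of the gene's predicted map vs the target
    map; ``rho_seed_mrna``: optional rho vs a designated seed gene's own
    predicted map; ``loocv_r``: Pearson r of the leave-one-out validation;
    ``sd``: standard deviation of the predicted map over masked sites;
    ``rsv``: relative structured variability (%).
    """

    gene_id: str
    rho_target: float = np.nan
    loocv_r: float = np.nan
    sd: float = np.nan
    rsv: float = np.nan
    rho_seed_mrna: float = np.nan
    entrez_id: int | None = None

    def __post_init__(self):
        for name in ("rho_target", "loocv_r", "rho_seed_mrna"):
            v = getattr(self, name)
            if np.isfinite(v) and not -1.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"gene {self.gene_id}: {name}={v} outside [-1, 1]")
        if np.isfinite(self.sd) and self.sd < 0:
            raise ValueError(f"gene {self.gene_id}: sd must be >= 0")
        if np.isfinite(self.rsv) and not 0 <= self.rsv <= 100 + 1e-9:
            raise ValueError(f"gene {self.gene_id}: rsv must be in [0, 100]")


@dataclass
class ScreenConfig:
    """Thresholds and comparison conventions of the two-stage screen.

    The rho comparison defaults to >= ("genes with rho >= 0.7") and the
    cross-validation comparison to strict > ("r > 0.3").
    """

    rho_threshold: float = 0.7
    cv_threshold: float = 0.3
    rho_comparison: str = "ge"
    cv_comparison: str = "gt"

    def __post_init__(self):
        for name, v in (("rho_threshold", self.rho_threshold),
                        ("cv_threshold", self.cv_threshold)):
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1); got {v}")
        for name, v in (("rho_comparison", self.rho_comparison),
                        ("cv_comparison", self.cv_comparison)):
            if v not in ("ge", "gt"):
                raise ConfigurationError(f"{name} must be 'ge' or 'gt'; got {v!r}")


def _passes(value: float, threshold: float, comparison: str) -> bool:
    if not np.isfinite(value):
        return False
    return value >= threshold if comparison == "ge" else value > threshold


def spearman_map_correlation(
    map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Spearman's rho between two index-aligned maps over masked sites.

    Mid-ranks (average ranks) are used for ties, the standard definition.
    Zero rank variance in either map makes rho undefined: NaN is returned
    with a warning and such genes are excluded downstream.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"maps are not index-aligned: {a.shape} vs {b.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        a, b = a[mask], b[mask]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError(f"need >= 3 masked sites for Spearman, got {len(a)}")
    ra = stats.rankdata(a)  # mid-ranks
    rb = stats.rankdata(b)
    if np.std(ra) == 0 or np.std(rb) == 0:
        warnings.warn(
            "zero rank variance; Spearman undefined, returning NaN", stacklevel=2
        )
        return float("nan")
    return float(np.corrcoef(ra, rb)[0, 1])


def screen_genes(
    records: list[GeneRecord], config: ScreenConfig | None = None
) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Apply the two-threshold screen; return passers plus an audit log.

    Passers are sorted by rho_target descending, ties broken by gene_id
    ascending.  The audit log records, per gene, each check's outcome and
    the reason for exclusion (including missing statistics).
    """
    config = config or ScreenConfig()
    audit_rows = []
    passed = []
    for rec in records:
        missing = [
            name
            for name, v in (("rho_target", rec.rho_target), ("loocv_r", rec.loocv_r))
            if not np.isfinite(v)
        ]
        rho_ok = _passes(rec.rho_target, config.rho_threshold, config.rho_comparison)
        cv_ok = _passes(rec.loocv_r, config.cv_threshold, config.cv_comparison)
        if missing:
            reason = f"missing statistic(s): {', '.join(missing)}"
        elif rho_ok and cv_ok:
            reason = "pass"
        else:
            fails = []
            op = ">=" if config.rho_comparison == "ge" else ">"
            if not rho_ok:
                fails.append(f"rho_target {rec.rho_target:.3f} not {op} {config.rho_threshold}")
            opc = ">=" if config.cv_comparison == "ge" else ">"
            if not cv_ok:
                fails.append(f"loocv_r {rec.loocv_r:.3f} not {opc} {config.cv_threshold}")
            reason = "; ".join(fails)
        audit_rows.append(
            {
                "gene_id": rec.gene_id,
                "rho_target": rec.rho_target,
                "loocv_r": rec.loocv_r,
                "rho_pass": rho_ok,
                "cv_pass": cv_ok,
                "passed": rho_ok and cv_ok and not missing,
                "reason": reason,
            }
        )
        if rho_ok and cv_ok and not missing:
            passed.append(rec)
    passed.sort(key=lambda r: (-r.rho_target, r.gene_id))
    return passed, pd.DataFrame(audit_rows)
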