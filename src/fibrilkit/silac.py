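"""Protein half-life estimation from pulse SILAC heavy/light peptide tables.

A heavy-lysine pulse of length ``pulse_h`` marks protein synthesized during
the pulse; pre-existing protein stays light and is lost both by degradation
(rate constant ``k``) and by dilution through cell division (doubling time
``doubling_h``).  Under the assumptions that no new light protein is made
during the pulse, that light protein decays exponentially, and that total
protein doubles once per cell cycle, the heavy/light intensity ratio HL of a
protein's peptides determines its decay constant::

    k = ln(HL + 1) / pulse_h  -  ln(2) / doubling_h
    t_half = ln(2) / k

An HL at or below ``2**(pulse_h/doubling_h) - 1`` implies k <= 0: the
protein is lost no faster than division dilutes it, and its half-life is not
estimable under the model (reported as censored, never as a negative time).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TurnoverConfig",
    "ProteinTurnoverEstimate",
    "censoring_threshold",
    "filter_proteins",
    "protein_hl_ratio",
    "turnover_estimate",
    "implied_light_fraction",
    "run_turnover",
    "read_peptide_table",
    "write_estimates",
]

logger = logging.getLogger(__name__)

#: Required columns of a peptide-level SILAC quantification table.
PEPTIDE_COLUMNS = ("protein_id", "peptide", "channel", "intensity", "replicate")

CHANNELS = frozenset({"heavy", "light"})


@dataclass(frozen=True)
class TurnoverConfig:
    """Pulse design and evidence filters for half-life estimation.

    Parameters
    ----------
    pulse_h
        Duration of the heavy-label pulse in hours.
    doubling_h
        Cell population doubling time in hours; division dilutes the
        pre-existing light pool at rate ln(2)/doubling_h.
    min_peptides
        Minimum peptide observations (pooled over replicates) per protein.
    min_heavy
        Minimum heavy-channel observations per protein.
    min_replicates
        Minimum distinct replicates a protein must appear in.
    ratio_method
        ``"intensity-sum"``: HL = sum(heavy)/sum(light) over all peptides;
        ``"peptide-median"``: median over peptides seen in both channels of
        their per-peptide heavy/light ratio.
    peptide_unit
        ``"observations"`` counts every (peptide, channel, replicate) row
        toward ``min_peptides``; ``"sequences"`` counts distinct sequences.
    """

    pulse_h: float = 48.0
    doubling_h: float = 72.0
    min_peptides: int = 3
    min_heavy: int = 1
    min_replicates: int = 2
    ratio_method: str = "intensity-sum"
    peptide_unit: str = "observations"

    def __post_init__(self) -> None:
        if self.pulse_h <= 0 or self.doubling_h <= 0:
            raise ValueError("pulse_h and doubling_h must be positive")
        if min(self.min_peptides, self.min_heavy, self.min_replicates) < 0:
            raise ValueError("evidence minima must be non-negative")
        if self.ratio_method not in ("intensity-sum", "peptide-median"):
            raise ValueError(f"unknown ratio_method {self.ratio_method!r}")
        if self.peptide_unit not in ("observations", "sequences"):
            raise ValueError(f"unknown peptide_unit {self.peptide_unit!r}")

    @property
    def dilution_rate(self) -> float:
        """Division-dilution rate ln(2)/doubling_h in 1/h."""
        return math.log(2.0) / self.doubling_h


@dataclass
class ProteinTurnoverEstimate:
    """Half-life estimate for one protein.

    ``censored`` is True when HL <= 2**(pulse/doubling) - 1 (k <= 0, decay
    not distinguishable from division dilution) or when no light signal was
    detected (HL unbounded above; half-life below detection).
    """

    protein_id: str
    HL: float
    light_fraction: float
    k_per_h: float
    t_half_h: float
    censored: bool
    censor_reason: str = ""
    n_peptides: int = 0
    n_heavy: int = 0
    n_replicates: int = 0


def censoring_threshold(config: TurnoverConfig) -> float:
    """HL value at which k is exactly zero: 2**(pulse/doubling) - 1."""
    return 2.0 ** (config.pulse_h / config.doubling_h) - 1.0


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in PEPTIDE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    bad_channel = ~table["channel"].isin(CHANNELS)
    if bad_channel.any():
        rows = table.index[bad_channel].tolist()[:10]
        raise ValueError(f"invalid channel values at rows {rows}")
    neg = table["intensity"] < 0
    if neg.any():
        rows = table.index[neg].tolist()[:10]
        raise ValueError(f"negative intensities at rows {rows}")


def filter_proteins(
    table: pd.DataFrame, config: TurnoverConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the evidence filter; return (retained rows, rejection report).

    A protein is retained iff it has at least ``min_peptides`` peptide
    observations pooled over replicates, at least ``min_heavy`` of them in
    the heavy channel, and appears in at least ``min_replicates`` distinct
    replicates.  The report lists one row per rejected protein with the
    first criterion it failed.
    """
    config = config or TurnoverConfig()
    if table.empty:
        logger.warning("empty peptide table: nothing to filter")
        report = pd.DataFrame(columns=["protein_id", "reason"])
        return table.copy(), report
    _validate_table(table)

    rejected: list[tuple[str, str]] = []
    keep: list[str] = []
    for pid, grp in table.groupby("protein_id", sort=True):
        if config.peptide_unit == "sequences":
            n_pep = grp["peptide"].nunique()
        else:
            n_pep = len(grp)
        n_heavy = int((grp["channel"] == "heavy").sum())
        n_reps = grp["replicate"].nunique()
        if n_pep < config.min_peptides:
            rejected.append((pid, f"peptides {n_pep} < {config.min_peptides}"))
        elif n_heavy < config.min_heavy:
            rejected.append((pid, f"heavy observations {n_heavy} < {config.min_heavy}"))
        elif n_reps < config.min_replicates:
            rejected.append((pid, f"replicates {n_reps} < {config.min_replicates}"))
        else:
            keep.append(pid)

    retained = table[table["protein_id"].isin(keep)].copy()
    report = pd.DataFrame(rejected, columns=["protein_id", "reason"])
    return retained, report


def protein_hl_ratio(records: pd.DataFrame, method: str = "intensity-sum") -> float:
    """Heavy/light ratio for one protein's peptide records.

    intensity-sum: HL = sum of heavy intensities / sum of light intensities.
    peptide-median: median over peptides quantified in both channels of
    (summed heavy / summed light) per peptide.

    Returns ``math.inf`` when the light signal is zero (below-detection
    censoring, handled downstream) and ``nan`` when no usable ratio exists.
    """
    heavy = records.loc[records["channel"] == "heavy", "intensity"]
    light = records.loc[records["channel"] == "light", "intensity"]
    if method == "intensity-sum":
        light_sum = float(light.sum())
        heavy_sum = float(heavy.sum())
        if light_sum == 0.0:
            return math.inf if heavy_sum > 0 else math.nan
        return heavy_sum / light_sum
    if method == "peptide-median":
        per_pep = records.pivot_table(
            index="peptide", columns="channel", values="intensity", aggfunc="sum"
        )
        if "heavy" not in per_pep.columns or "light" not in per_pep.columns:
            return math.nan
        both = per_pep.dropna(subset=["heavy", "light"])
        both = both[both["light"] > 0]
        if both.empty:
            return math.inf if float(heavy.sum()) > 0 else math.nan
        return float((both["heavy"] / both["light"]).median())
    raise ValueError(f"unknown ratio method {method!r}")


def turnover_estimate(
    HL: float, config: TurnoverConfig | None = None, protein_id: str = ""
) -> ProteinTurnoverEstimate:
    """Convert an HL ratio into decay constant and half-life.

    k = ln(HL + 1)/pulse_h - ln(2)/doubling_h; t_half = ln(2)/k when k > 0.
    HL = inf (no light detected) censors as below-detection; k <= 0 censors
    as at-or-beyond the dilution-only bound.
    """
    config = config or TurnoverConfig()
    if math.isinf(HL):
        f = 0.0
        return ProteinTurnoverEstimate(
            protein_id, math.inf, f, math.nan, math.nan,
            censored=True, censor_reason="no light signal (half-life below detection)",
        )
    if not math.isfinite(HL) or HL < 0:
        raise ValueError(f"HL must be finite and non-negative, got {HL}")
    k = math.log(HL + 1.0) / config.pulse_h - config.dilution_rate
    f = 1.0 / (HL + 1.0)
    if k > 0:
        return ProteinTurnoverEstimate(
            protein_id, HL, f, k, math.log(2.0) / k, censored=False
        )
    return ProteinTurnoverEstimate(
        protein_id, HL, f, k, math.nan,
        censored=True,
        censor_reason="k <= 0: not estimable (at or beyond dilution-only bound)",
    )


def implied_light_fraction(
    t_half: float, config: TurnoverConfig | None = None
) -> tuple[float, float]:
    """Invert the half-life equations: expected (light fraction f, HL).

    f = exp(-(ln2/t_half + ln2/doubling_h) * pulse_h); HL = 1/f - 1.
    As t_half -> inf, f approaches the dilution-only limit
    2**(-pulse_h/doubling_h).
    """
    config = config or TurnoverConfig()
    if not t_half > 0:
        raise ValueError(f"t_half must be positive, got {t_half}")
    ln2 = math.log(2.0)
    rate = ln2 / t_half + ln2 / config.doubling_h
    f = math.exp(-rate * config.pulse_h)
    return f, 1.0 / f - 1.0


def run_turnover(
    table: pd.DataFrame, config: TurnoverConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Full pipeline: filter, per-protein HL, half-life, and summary.

    Returns an estimates table (one row per retained protein) and a summary
    dict with retention/censoring counts and half-life distribution
    quantiles over the uncensored proteins.
    """
    config = config or TurnoverConfig()
    retained, report = filter_proteins(table, config)
    rows = []
    for pid, grp in retained.groupby("protein_id", sort=True):
        hl = protein_hl_ratio(grp, config.ratio_method)
        if math.isnan(hl):
            logger.warning("protein %s: no usable HL ratio, skipped", pid)
            continue
        est = turnover_estimate(hl, config, protein_id=pid)
        est.n_peptides = len(grp)
        est.n_heavy = int((grp["channel"] == "heavy").sum())
        est.n_replicates = grp["replicate"].nunique()
        rows.append(est)

    estimates = pd.DataFrame(
        [
            {
                "protein_id": e.protein_id,
                "n_peptides": e.n_peptides,
                "n_heavy": e.n_heavy,
                "n_replicates": e.n_replicates,
                "HL": e.HL,
                "light_fraction": e.light_fraction,
                "k_per_h": e.k_per_h,
                "t_half_h": e.t_half_h,
                "censored": e.censored,
                "censor_reason": e.censor_reason,
            }
            for e in rows
        ],
        columns=[
            "protein_id", "n_peptides", "n_heavy", "n_replicates", "HL",
            "light_fraction", "k_per_h", "t_half_h", "censored", "censor_reason",
        ],
    )
    ok = estimates.loc[~estimates["censored"].astype(bool), "t_half_h"] if len(estimates) else pd.Series(dtype=float)
    summary = {
        "n_input_proteins": int(table["protein_id"].nunique()) if len(table) else 0,
        "n_retained": int(estimates["protein_id"].nunique()) if len(estimates) else 0,
        "n_rejected": int(len(report)),
        "n_censored": int(estimates["censored"].sum()) if len(estimates) else 0,
        "t_half_median_h": float(ok.median()) if len(ok) else math.nan,
        "t_half_q25_h": float(ok.quantile(0.25)) if len(ok) else math.nan,
        "t_half_q75_h": float(ok.quantile(0.75)) if len(ok) else math.nan,
        "pulse_h": config.pulse_h,
        "doubling_h": config.doubling_h,
        "ratio_method": config.ratio_method,
    }
    return estimates, summary


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read a peptide TSV (`protein_id  peptide  channel  intensity  replicate`)."""
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "peptide": str, "channel": str})
    _validate_table(table)
    return table


def write_estimates(estimates: pd.DataFrame, path: str | Path) -> None:
    estimates.to_csv(path, sep="\t", index=False)
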