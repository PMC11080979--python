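"""Case-control likelihood ratios and ACMG/AMP evidence strengths.

The case-control likelihood ratio (ccLR) compares the probability of the
observed carrier/status/age data under the hypothesis that the variant
carries the age-specific risks of the "average" pathogenic variant in the
gene (H_p) against the hypothesis that it confers no risk increase (H_b).
Conditioning on the number of carriers ``K`` among ``N`` individuals, the
ratio reduces to

    ccLR = prod_{j: v_j = 1} w(t_j, d_j) / ( (1/N) sum_j w(t_j, d_j) )^K

where ``w(t, d) = S_1(t) exp(beta(t) d) / S_0(t)`` is the per-individual
carrier-vs-non-carrier weight from the penetrance model. The LR is
computed in log space so that very large and very small ratios survive
floating point. Per-stratum (e.g. per-country) LRs multiply into an
overall LR, guarding against carrier-frequency differences between
populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .penetrance import PenetranceModel

__all__ = [
    "Individual",
    "CaseControlDataset",
    "StratumLR",
    "LikelihoodRatioResult",
    "FilterReport",
    "filter_dataset",
    "stratum_lr",
    "combined_lr",
    "acmg_strength",
    "ACMG_ORDER",
    "screen_carrier_frequency",
    "CarrierFrequencyWarning",
    "FrequencyError",
    "FLAG_NO_CARRIERS",
]

FLAG_NO_CARRIERS = "no carriers"


@dataclass(frozen=True)
class Individual:
    """One study subject: carrier status, disease status, age, optional stratum.

    ``age`` is the age at diagnosis for cases and at interview for
    controls; ``None``/NaN marks unknown age.
    """

    carrier: int
    status: int
    age: float | None = None
    stratum: str | None = None

    @property
    def age_known(self) -> bool:
        return self.age is not None and np.isfinite(self.age)


class CaseControlDataset:
    """Individual-level case-control data backed by a pandas DataFrame.

    Columns: ``carrier`` (0/1), ``status`` (0 control / 1 case), ``age``
    (years; NaN = unknown), ``stratum`` (optional country/study label).
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = ""):
        f = pd.DataFrame(frame).copy()
        for col in ("carrier", "status"):
            if col not in f.columns:
                raise ValueError(f"dataset requires a {col!r} column")
            bad = ~f[col].isin([0, 1])
            if bad.any():
                rows = list(f.index[bad][:5])
                raise ValueError(f"non-binary {col!r} values at rows {rows}")
            f[col] = f[col].astype(np.int8)
        if "age" not in f.columns:
            f["age"] = np.nan
        f["age"] = pd.to_numeric(f["age"]).astype(float)
        if "stratum" not in f.columns:
            f["stratum"] = None
        self.frame = f.loc[:, ["carrier", "status", "age", "stratum"]].reset_index(
            drop=True
        )
        self.provenance = provenance
        if len(self.frame) < 1:
            raise ValueError("dataset must contain at least one individual")

    @classmethod
    def from_individuals(cls, individuals, provenance: str = ""):
        rows = [
            (i.carrier, i.status, np.nan if i.age is None else i.age, i.stratum)
            for i in individuals
        ]
        return cls(
            pd.DataFrame(rows, columns=["carrier", "status", "age", "stratum"]),
            provenance,
        )

    @classmethod
    def from_arrays(cls, carrier, status, age, stratum=None, provenance: str = ""):
        f = pd.DataFrame({"carrier": carrier, "status": status, "age": age})
        f["stratum"] = stratum if stratum is not None else None
        return cls(f, provenance)

    def __len__(self):
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def k(self) -> int:
        """Number of variant carriers."""
        return int(self.frame["carrier"].sum())

    @property
    def n_cases(self) -> int:
        return int(self.frame["status"].sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    @property
    def carrier_frequency(self) -> float:
        return self.k / self.n


# ---------------------------------------------------------------------------
# Age filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Exclusion/assignment bookkeeping from :func:`filter_dataset`."""

    n_input: int
    n_age_out_of_range: int
    n_unknown_excluded: int
    n_unknown_assigned: int
    assigned_age: float | None
    n_output: int


def oldest_band_age(model: PenetranceModel) -> float:
    """Midpoint of the oldest incidence band intersected with the permitted range."""
    lo, hi = model.age_range
    edges = model.incidence.age_breaks
    i = int(np.clip(np.searchsorted(edges, hi, side="right") - 1, 0, edges.size - 2))
    start = max(float(edges[i]), lo)
    end = min(float(edges[i + 1]), hi)
    return 0.5 * (start + end)


def filter_dataset(
    data: CaseControlDataset,
    model: PenetranceModel,
    unknown_age_policy="oldest",
) -> tuple[CaseControlDataset, FilterReport]:
    """Drop individuals outside the permitted age range; route unknown ages.

    Ages strictly outside the inclusive ``model.age_range`` are removed
    and counted. Unknown-age individuals are either excluded
    (``policy='exclude'``), assigned the representative age of the oldest
    band (``policy='oldest'``, the conservative choice: it down-weights
    their contribution), or assigned a fixed numeric age.
    """
    lo, hi = model.age_range
    f = data.frame
    known = f["age"].notna() & np.isfinite(f["age"].fillna(np.inf))
    in_range = known & (f["age"] >= lo) & (f["age"] <= hi)
    n_out = int((known & ~in_range).sum())
    n_unknown = int((~known).sum())

    if unknown_age_policy == "exclude":
        keep = f[in_range].copy()
        assigned = None
        n_assigned, n_unk_excluded = 0, n_unknown
    else:
        if unknown_age_policy == "oldest":
            assigned = oldest_band_age(model)
        else:
            assigned = float(unknown_age_policy)
            if not lo <= assigned <= hi:
                raise ValueError(
                    f"assigned age {assigned} outside permitted range [{lo}, {hi}]"
                )
        keep = f[in_range | ~known].copy()
        keep.loc[keep["age"].isna(), "age"] = assigned
        n_assigned, n_unk_excluded = n_unknown, 0

    if len(keep) == 0:
        raise ValueError("no individuals remain after age filtering")
    out = CaseControlDataset(keep, provenance=data.provenance)
    report = FilterReport(
        n_input=len(f),
        n_age_out_of_range=n_out,
        n_unknown_excluded=n_unk_excluded,
        n_unknown_assigned=n_assigned,
        assigned_age=assigned if n_assigned else None,
        n_output=len(out),
    )
    return out, report


# ---------------------------------------------------------------------------
# Carrier-frequency screen
# ---------------------------------------------------------------------------


class CarrierFrequencyWarning(UserWarning):
    pass


class FrequencyError(ValueError):
    pass


def screen_carrier_frequency(
    data: CaseControlDataset, threshold: float = 0.001, hard: bool = False
) -> float:
    """Warn (or refuse, ``hard=True``) if the variant is too frequent.

    The ccLR is designed for rare variants; variants above the threshold
    carrier frequency (default 0.1%) should be excluded from this kind of
    analysis.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    freq = data.carrier_frequency
    if freq > threshold:
        msg = (
            f"carrier frequency {freq:.3g} exceeds the rare-variant threshold "
            f"{threshold:g}; the ccLR is not designed for common variants"
        )
        if hard:
            raise FrequencyError(msg)
        warnings.warn(msg, CarrierFrequencyWarning, stacklevel=2)
    return freq


# ---------------------------------------------------------------------------
# Likelihood ratio
# ---------------------------------------------------------------------------


@dataclass
class StratumLR:
    lr: float
    log_lr: float
    k: int
    n: int
    flags: list = field(default_factory=list)


@dataclass
class LikelihoodRatioResult:
    """Overall ccLR with per-stratum detail and ACMG/AMP strength."""

    lr: float
    log_lr: float
    k_total: int
    n_total: int
    strength: str
    per_stratum: dict
    flags: list = field(default_factory=list)


def _stratum_log_lr(frame: pd.DataFrame, model: PenetranceModel) -> StratumLR:
    ages = frame["age"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ages)):
        raise ValueError(
            "dataset contains unknown or non-finite ages; apply filter_dataset first"
        )
    d = frame["status"].to_numpy()
    v = frame["carrier"].to_numpy()
    n = ages.size
    k = int(v.sum())
    if k == 0:
        # empty product over carriers and exponent zero: LR exactly 1
        return StratumLR(1.0, 0.0, 0, n, [FLAG_NO_CARRIERS])
    logw = model.log_weight(ages, d)
    log_mean = logsumexp(logw) - np.log(n)
    log_lr = float(np.sum(logw[v == 1]) - k * log_mean)
    return StratumLR(float(np.exp(log_lr)), log_lr, k, n, [])


def stratum_lr(data: CaseControlDataset, model: PenetranceModel) -> float:
    """ccLR for a single stratum; exactly 1 when there are no carriers."""
    return _stratum_log_lr(data.frame, model).lr


def combined_lr(
    data: CaseControlDataset,
    model: PenetranceModel,
    stratify_by: str | None = None,
) -> LikelihoodRatioResult:
    """Overall ccLR, optionally as a product of per-stratum LRs.

    ``stratify_by='stratum'`` computes the LR within each stratum label
    and multiplies; strata without carriers contribute a factor of 1.
    Every individual must carry a label when stratifying.
    """
    f = data.frame
    if stratify_by is None:
        parts = {"all": _stratum_log_lr(f, model)}
    elif stratify_by == "stratum":
        if f["stratum"].isna().any():
            n_missing = int(f["stratum"].isna().sum())
            raise ValueError(
                f"stratified analysis requested but {n_missing} individual(s) "
                "lack a stratum label"
            )
        parts = {
            str(lab): _stratum_log_lr(g, model)
            for lab, g in f.groupby("stratum", sort=True)
        }
    else:
        raise ValueError("stratify_by must be None or 'stratum'")

    log_lr = float(sum(p.log_lr for p in parts.values()))
    k_total = sum(p.k for p in parts.values())
    n_total = sum(p.n for p in parts.values())
    lr = float(np.exp(log_lr))
    flags = [FLAG_NO_CARRIERS] if k_total == 0 else []
    return LikelihoodRatioResult(
        lr=lr,
        log_lr=log_lr,
        k_total=k_total,
        n_total=n_total,
        strength=acmg_strength(lr),
        per_stratum=parts,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# ACMG/AMP evidence strength
# ---------------------------------------------------------------------------

# LR bins calibrated to ACMG/AMP evidence strengths; lower bounds of the
# pathogenic bins and upper bounds of the benign bins are inclusive.
_PATHOGENIC_BINS = (
    (350.0, "pathogenic_very_strong"),
    (18.7, "pathogenic_strong"),
    (4.33, "pathogenic_moderate"),
    (2.08, "pathogenic_supporting"),
)
_BENIGN_BINS = (
    (0.0029, "benign_very_strong"),
    (0.053, "benign_strong"),
    (0.231, "benign_moderate"),
    (0.48, "benign_supporting"),
)

ACMG_ORDER = (
    "benign_very_strong",
    "benign_strong",
    "benign_moderate",
    "benign_supporting",
    "none",
    "pathogenic_supporting",
    "pathogenic_moderate",
    "pathogenic_strong",
    "pathogenic_very_strong",
)


def acmg_strength(lr: float) -> str:
    """Map an LR to its ACMG/AMP evidence strength code.

    Pathogenic: very strong LR >= 350; strong >= 18.7; moderate >= 4.33;
    supporting >= 2.08. Benign: very strong LR <= 0.0029; strong <= 0.053;
    moderate <= 0.231; supporting <= 0.48. LRs strictly between 0.48 and
    2.08 carry no evidence strength (``'none'``).
    """
    lr = float(lr)
    if not np.isfinite(lr) or lr <= 0:
        raise ValueError(f"LR must be a positive finite number, got {lr!r}")
    for bound, code in _PATHOGENIC_BINS:
        if lr >= bound:
            return code
    for bound, code in _BENIGN_BINS:
        if lr <= bound:
            return code
    return "none"
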