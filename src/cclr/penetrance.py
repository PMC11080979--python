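"""Piecewise-constant age-specific penetrance models.

The disease model is a proportional-hazards survival model on age. A
genotype ``k`` (0 = non-carrier, 1 = carrier of the variant under test)
experiences the hazard ``lambda_0(t) * exp(beta(t) * k)``, where
``lambda_0(t)`` is the baseline (population) disease incidence per
person-year and ``exp(beta(t))`` is the age-specific relative risk of the
hypothesized "average" pathogenic variant in the gene of interest. Both
curves are piecewise constant on half-open age bands ``[a_i, a_{i+1})``,
matching the banded form in which incidence rates and relative risks are
published; no interpolation between bands is performed.

From the hazard, the probability of remaining unaffected at age ``t`` is

    S_k(t) = exp(-integral_0^t lambda_0(u) exp(beta(u) k) du)

and the only quantity the case-control likelihood ratio needs per
individual is the carrier-vs-non-carrier weight

    w(t, d) = S_1(t) exp(beta(t) d) / S_0(t)

with ``d`` the disease status (the baseline hazard cancels in the ratio,
so an affected individual's density term contributes only the relative
risk at the age at diagnosis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoverageError",
    "IncidenceTable",
    "RelativeRiskCurve",
    "PenetranceModel",
    "bundled_model",
    "BUNDLED_GENES",
]


class CoverageError(ValueError):
    """An age falls outside the range covered by the penetrance tables."""


def _validated_edges(age_breaks, n_values: int, what: str) -> np.ndarray:
    edges = np.atleast_1d(np.asarray(age_breaks, dtype=float))
    if edges.size != n_values + 1:
        raise ValueError(
            f"{what}: {n_values} interval(s) need {n_values + 1} age breaks, "
            f"got {edges.size}"
        )
    if not np.all(np.isfinite(edges)) or not np.all(np.diff(edges) > 0):
        raise ValueError(f"{what}: age breaks must be finite and strictly increasing")
    if edges[0] < 0:
        raise ValueError(f"{what}: ages must be nonnegative")
    return edges


@dataclass(frozen=True)
class IncidenceTable:
    """Baseline disease incidence, piecewise constant on age bands.

    Parameters
    ----------
    age_breaks
        Ordered ages in years defining half-open intervals
        ``[a_i, a_{i+1})``; length = number of rates + 1.
    rate_per_year
        Baseline incidence per person-year on each interval.
    """

    age_breaks: np.ndarray
    rate_per_year: np.ndarray

    def __post_init__(self):
        rates = np.atleast_1d(np.asarray(self.rate_per_year, dtype=float))
        if rates.size < 1:
            raise ValueError("IncidenceTable: at least one interval required")
        edges = _validated_edges(self.age_breaks, rates.size, "IncidenceTable")
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise ValueError("IncidenceTable: rates must be finite and nonnegative")
        object.__setattr__(self, "age_breaks", edges)
        object.__setattr__(self, "rate_per_year", rates)

    @classmethod
    def constant(cls, rate: float, age_min: float = 0.0, age_max: float = 80.0):
        """Single constant rate over ``[age_min, age_max]``."""
        return cls(np.array([age_min, age_max]), np.array([rate]))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.age_breaks[0]), float(self.age_breaks[-1])


@dataclass(frozen=True)
class RelativeRiskCurve:
    """Age-specific log relative risk beta(t) of the hypothesized pathogenic state.

    ``beta(t) = 0`` everywhere encodes the benign hypothesis. Relative risks
    published per age band as ORs/RRs should be supplied through
    :meth:`from_rr`; ORs for rare variants are treated as RRs.
    """

    age_breaks: np.ndarray
    log_rr: np.ndarray

    def __post_init__(self):
        logs = np.atleast_1d(np.asarray(self.log_rr, dtype=float))
        if logs.size < 1:
            raise ValueError("RelativeRiskCurve: at least one interval required")
        edges = _validated_edges(self.age_breaks, logs.size, "RelativeRiskCurve")
        if not np.all(np.isfinite(logs)):
            raise ValueError("RelativeRiskCurve: log relative risks must be finite")
        object.__setattr__(self, "age_breaks", edges)
        object.__setattr__(self, "log_rr", logs)

    @classmethod
    def from_rr(cls, age_breaks, rr):
        rr = np.atleast_1d(np.asarray(rr, dtype=float))
        if np.any(rr <= 0):
            raise ValueError("relative risks must be positive")
        return cls(np.asarray(age_breaks, dtype=float), np.log(rr))

    @classmethod
    def constant(cls, rr: float, age_min: float = 0.0, age_max: float = 80.0):
        return cls.from_rr([age_min, age_max], [rr])

    @classmethod
    def null(cls, age_min: float = 0.0, age_max: float = 80.0):
        """beta(t) = 0 everywhere: the benign hypothesis."""
        return cls(np.array([age_min, age_max]), np.array([0.0]))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.age_breaks[0]), float(self.age_breaks[-1])


def _band_lookup(edges: np.ndarray, values: np.ndarray, x: np.ndarray,
                 fill: float | str) -> np.ndarray:
    """Value of a piecewise-constant table at points ``x``.

    ``fill=0.0`` returns 0 outside the table's span (used for incidence:
    no disease incidence assumed before the first band); ``fill='edge'``
    extends the first/last band outward (used for the relative-risk curve,
    which only matters outside its span where incidence is nonzero).
    """
    idx = np.searchsorted(edges, x, side="right") - 1
    if fill == "edge":
        return values[np.clip(idx, 0, values.size - 1)]
    out = np.where(
        (idx >= 0) & (idx < values.size), values[np.clip(idx, 0, values.size - 1)], fill
    )
    return out


class PenetranceModel:
    """Genotype-specific survival and likelihood weights under proportional hazards.

    Parameters
    ----------
    incidence
        Baseline incidence table; must cover ``age_range``.
    rr_curve
        Age-specific log relative risk; must cover ``age_range``.
    age_range
        Inclusive ``[min, max]`` ages permitted for individuals in an
        analysis (default 21-80, the range over which penetrance estimates
        are typically available).

    Notes
    -----
    The cumulative hazard integrates from age 0. If the incidence table
    starts above 0 the hazard below its first band is taken to be zero;
    if the relative-risk curve starts above 0 its first band is extended
    downward (this only matters where incidence is nonzero).
    """

    def __init__(self, incidence: IncidenceTable, rr_curve: RelativeRiskCurve,
                 age_range: tuple[float, float] = (21.0, 80.0)):
        lo, hi = float(age_range[0]), float(age_range[1])
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        inc_lo, inc_hi = incidence.span
        rr_lo, rr_hi = rr_curve.span
        gaps = []
        if inc_lo > lo or inc_hi < hi:
            gaps.append(f"incidence covers [{inc_lo}, {inc_hi}]")
        if rr_lo > lo or rr_hi < hi:
            gaps.append(f"relative-risk curve covers [{rr_lo}, {rr_hi}]")
        if gaps:
            raise CoverageError(
                f"penetrance tables must cover the permitted age range "
                f"[{lo}, {hi}]: " + "; ".join(gaps)
            )
        self.incidence = incidence
        self.rr_curve = rr_curve
        self.age_range = (lo, hi)
        self._build_segments()

    @classmethod
    def constant(cls, baseline_rate: float, rr: float,
                 age_range: tuple[float, float] = (21.0, 80.0)):
        """Constant baseline rate and constant relative risk from age 0."""
        hi = float(age_range[1])
        return cls(
            IncidenceTable.constant(baseline_rate, 0.0, hi),
            RelativeRiskCurve.constant(rr, 0.0, hi),
            age_range,
        )

    # -- internal piecewise machinery -------------------------------------

    def _build_segments(self):
        cov_end = min(self.incidence.span[1], self.rr_curve.span[1])
        edges = np.union1d(self.incidence.age_breaks, self.rr_curve.age_breaks)
        edges = np.union1d(edges, [0.0])
        edges = edges[edges <= cov_end]
        mids = 0.5 * (edges[:-1] + edges[1:])
        rate = _band_lookup(
            self.incidence.age_breaks, self.incidence.rate_per_year, mids, fill=0.0
        )
        beta = _band_lookup(
            self.rr_curve.age_breaks, self.rr_curve.log_rr, mids, fill="edge"
        )
        widths = np.diff(edges)
        self._edges = edges
        self._rate = rate
        self._beta = beta
        self._cum = {
            k: np.concatenate([[0.0], np.cumsum(rate * np.exp(beta * k) * widths)])
            for k in (0, 1)
        }
        self._cov_end = float(cov_end)

    @staticmethod
    def _as_array(t):
        arr = np.asarray(t, dtype=float)
        return np.atleast_1d(arr), arr.ndim == 0

    def _check_coverage(self, t_arr):
        if not np.all(np.isfinite(t_arr)):
            raise CoverageError("ages must be finite")
        if np.any(t_arr < 0) or np.any(t_arr > self._cov_end):
            bad = t_arr[(t_arr < 0) | (t_arr > self._cov_end)]
            raise CoverageError(
                f"age(s) {bad[:5].tolist()} outside the covered interval "
                f"[0, {self._cov_end}]"
            )

    def _check_range(self, t_arr):
        lo, hi = self.age_range
        bad_mask = ~np.isfinite(t_arr) | (t_arr < lo) | (t_arr > hi)
        if np.any(bad_mask):
            bad = t_arr[bad_mask]
            raise CoverageError(
                f"age(s) {bad[:5].tolist()} outside the permitted age range "
                f"[{lo}, {hi}]"
            )

    # -- public surface ----------------------------------------------------

    def cumulative_hazard(self, t, k: int):
        """Integral of ``lambda_0(u) exp(beta(u) k)`` over ``[0, t]``.

        Evaluated exactly as a sum of rate x width terms over the piecewise
        bands; additive over adjacent intervals.
        """
        if k not in (0, 1):
            raise ValueError("genotype k must be 0 (non-carrier) or 1 (carrier)")
        t_arr, scalar = self._as_array(t)
        self._check_coverage(t_arr)
        idx = np.clip(
            np.searchsorted(self._edges, t_arr, side="right") - 1, 0, self._rate.size - 1
        )
        h = self._cum[k][idx] + self._rate[idx] * np.exp(self._beta[idx] * k) * (
            t_arr - self._edges[idx]
        )
        return float(h[0]) if scalar else h

    def survival_probability(self, t, k: int):
        """S_k(t) = exp(-cumulative hazard); in (0, 1], non-increasing in t."""
        return np.exp(-self.cumulative_hazard(t, k))

    def log_rr_at(self, t):
        """beta(t) at the band containing each age (edge bands extended)."""
        t_arr, scalar = self._as_array(t)
        beta = _band_lookup(self.rr_curve.age_breaks, self.rr_curve.log_rr,
                            t_arr, fill="edge")
        # ages equal to the final break belong to the last band
        return float(beta[0]) if scalar else beta

    def log_weight(self, t, d):
        """log of the per-individual likelihood weight ``w(t, d)``.

        ``w(t, d) = S_1(t) exp(beta(t) d) / S_0(t)``; for affected
        individuals (``d = 1``) beta is evaluated at the band containing
        the age at diagnosis.
        """
        t_arr, scalar = self._as_array(t)
        self._check_range(t_arr)
        d_arr = np.asarray(d)
        if not np.all(np.isin(d_arr, (0, 1))):
            raise ValueError("disease status d must be 0 or 1")
        h0 = self.cumulative_hazard(t_arr, 0)
        h1 = self.cumulative_hazard(t_arr, 1)
        lw = (h0 - h1) + self.log_rr_at(t_arr) * d_arr
        return float(lw[0]) if scalar else lw

    def individual_weight(self, t, d):
        """Carrier-vs-non-carrier likelihood weight ``w(t, d) > 0``."""
        return np.exp(self.log_weight(t, d))

    def __repr__(self):  # pragma: no cover - cosmetic
        lo, hi = self.age_range
        return (
            f"PenetranceModel({self.incidence.rate_per_year.size} incidence band(s), "
            f"{self.rr_curve.log_rr.size} RR band(s), ages [{lo}, {hi}])"
        )


# ---------------------------------------------------------------------------
# Bundled illustrative curves
# ---------------------------------------------------------------------------
#
# Approximate stand-ins only: an England/Wales-style female breast cancer
# incidence shape and BRCA1/BRCA2-like relative-risk curves (high risk,
# attenuating with age). They are illustrative defaults for demonstrations
# and simulations; real analyses should supply published, gene-specific
# penetrance estimates through a penetrance configuration file.

_BASELINE_BREAKS = (0, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 81)
_BASELINE_RATES = (
    0.0, 1e-5, 8e-5, 2.5e-4, 6e-4, 1.2e-3, 1.8e-3,
    2.2e-3, 2.5e-3, 2.8e-3, 3.0e-3, 3.2e-3, 3.3e-3,
)

_RR_BREAKS = (0, 40, 50, 60, 70, 81)
_RR_BY_GENE = {
    "brca1": (11.0, 8.0, 5.5, 4.0, 3.0),
    "brca2": (5.9, 5.5, 4.9, 4.2, 3.5),
}
_RR_CONSTANT = {"brca1-constant": 10.0, "brca2-constant": 5.5}

BUNDLED_GENES = ("brca1", "brca2", "brca1-constant", "brca2-constant")


def bundled_model(name: str, age_range: tuple[float, float] = (21.0, 80.0)) -> PenetranceModel:
    """Illustrative, approximate penetrance model for a named gene profile.

    ``brca1``/``brca2`` carry age-attenuating relative-risk bands;
    ``brca1-constant`` (RR 10) and ``brca2-constant`` (RR 5.5) carry a
    single flat relative risk, the hypothesized curves used in the
    simulation studies. All share the same approximate baseline incidence
    shape. These are labeled stand-ins, not published estimates.
    """
    inc = IncidenceTable(np.array(_BASELINE_BREAKS, float),
                         np.array(_BASELINE_RATES, float))
    if name in _RR_BY_GENE:
        rrc = RelativeRiskCurve.from_rr(np.array(_RR_BREAKS, float), _RR_BY_GENE[name])
    elif name in _RR_CONSTANT:
        rrc = RelativeRiskCurve.constant(_RR_CONSTANT[name], 0.0, 81.0)
    else:
        raise ValueError(f"unknown bundled gene profile {name!r}; "
                         f"choose from {BUNDLED_GENES}")
    return PenetranceModel(inc, rrc, age_range)
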