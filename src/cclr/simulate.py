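"""Synthetic case-control genotype data and power / type-I-error studies.

Each simulated dataset has ``N`` cases and ``N`` controls. Carrier counts
per arm are Poisson with means

    lambda_cases = N * RR * MAF        lambda_controls = N * MAF

so the genotype signal enters only through the case/control carrier
imbalance. Ages are drawn per arm from a normal distribution (rounded to
whole years and clipped to the permitted range) independently of carrier
status, so age carries no signal in simulated data and the LR's age terms
act only through the penetrance weighting. A same-age mode assigns one
fixed age to everyone, emulating datasets with no age information.

Power for a criterion is the fraction of replicates meeting it; type-I
error is the same quantity under RR = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .comparators import ContingencySummary, OrResult, crude_or, logistic_or, ps4_criterion
from .likelihood import CaseControlDataset, combined_lr
from .penetrance import PenetranceModel

__all__ = [
    "Scenario",
    "PowerResult",
    "simulate_dataset",
    "evaluate_replicate",
    "replicate_lrs",
    "run_power_study",
    "CRITERIA",
    "METHOD_CRITERIA",
]

# decision criteria recorded per replicate
CRITERIA = {
    "lr_supporting_path": "ccLR >= 2.08 (at least supporting pathogenic)",
    "lr_strong_path": "ccLR >= 18.7 (at least strong pathogenic)",
    "lr_supporting_benign": "ccLR <= 0.48 (at least supporting benign)",
    "lr_strong_benign": "ccLR <= 0.053 (at least strong benign)",
    "ps4_logistic": "PS4 on age-adjusted logistic OR",
    "ps4_fisher": "PS4 on crude (Fisher/Haldane) OR",
}

METHOD_CRITERIA = {
    "cclr": (
        "lr_supporting_path",
        "lr_strong_path",
        "lr_supporting_benign",
        "lr_strong_benign",
    ),
    "logistic": ("ps4_logistic",),
    "fisher": ("ps4_fisher",),
}


@dataclass
class Scenario:
    """One simulation cell: sample size, relative risk, allele frequency.

    ``age_model`` is ``((mean, sd) cases, (mean, sd) controls)``. The
    defaults (cases 55 +- 10, controls 58 +- 10, clipped to 21-80) are
    approximate stand-ins for a population-based breast cancer
    case-control age structure.
    """

    n_per_arm: int
    rr: float
    maf: float
    age_model: tuple = ((55.0, 10.0), (58.0, 10.0))
    replicates: int = 10_000
    seed: int | None = None
    same_age_mode: bool = False
    same_age: float = 55.0
    age_range: tuple = (21.0, 80.0)

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be positive")
        if not 0 < self.maf < 0.001:
            raise ValueError("maf must be in (0, 0.001): the method targets rare variants")
        if self.rr < 1:
            raise ValueError("rr must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def lam_cases(self) -> float:
        return self.n_per_arm * self.rr * self.maf

    @property
    def lam_controls(self) -> float:
        return self.n_per_arm * self.maf


@dataclass
class PowerResult:
    """Estimated power or type-I error for one scenario x method x criterion."""

    n_per_arm: int
    rr: float
    maf: float
    same_age_mode: bool
    replicates: int
    seed: int | None
    method: str
    criterion: str
    proportion: float
    mc_se: float


def simulate_dataset(scenario: Scenario, rng: np.random.Generator | None = None) -> CaseControlDataset:
    """Draw one synthetic case-control dataset for a scenario.

    Carrier counts are Poisson (capped at N with a warning); carriers are
    assigned to uniformly chosen individuals within each arm; ages are
    rounded normal draws clipped to the permitted range, or one fixed age
    in same-age mode.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n = scenario.n_per_arm
    lam_c, lam_k = scenario.lam_cases, scenario.lam_controls
    if lam_c >= n or lam_k >= n:
        raise ValueError(
            f"scenario implies the allele is not rare (lambda {max(lam_c, lam_k):g} >= N {n})"
        )
    k_cases = int(rng.poisson(lam_c))
    k_controls = int(rng.poisson(lam_k))
    if k_cases > n or k_controls > n:
        warnings.warn("Poisson carrier draw exceeded N; capping at N", stacklevel=2)
        k_cases, k_controls = min(k_cases, n), min(k_controls, n)

    lo, hi = scenario.age_range
    if scenario.same_age_mode:
        ages_cases = np.full(n, float(scenario.same_age))
        ages_controls = np.full(n, float(scenario.same_age))
    else:
        (mc, sc), (mk, sk) = scenario.age_model
        ages_cases = np.clip(np.rint(rng.normal(mc, sc, n)), lo, hi)
        ages_controls = np.clip(np.rint(rng.normal(mk, sk, n)), lo, hi)

    carrier_cases = np.zeros(n, dtype=np.int8)
    carrier_cases[rng.choice(n, size=k_cases, replace=False)] = 1
    carrier_controls = np.zeros(n, dtype=np.int8)
    carrier_controls[rng.choice(n, size=k_controls, replace=False)] = 1

    frame = pd.DataFrame(
        {
            "carrier": np.concatenate([carrier_cases, carrier_controls]),
            "status": np.concatenate(
                [np.ones(n, dtype=np.int8), np.zeros(n, dtype=np.int8)]
            ),
            "age": np.concatenate([ages_cases, ages_controls]),
            "stratum": None,
        }
    )
    return CaseControlDataset(
        frame,
        provenance=(
            f"simulated (N={n} per arm, RR={scenario.rr}, MAF={scenario.maf}"
            + (", same-age" if scenario.same_age_mode else "")
            + ")"
        ),
    )


def evaluate_replicate(
    data: CaseControlDataset,
    model: PenetranceModel,
    methods=("cclr", "logistic", "fisher"),
) -> dict:
    """Analyze one replicate with the requested methods.

    Records the ccLR value, its ACMG/AMP bin and threshold flags, the
    age-adjusted logistic OR/CI/p (non-convergence flagged, not raised),
    the crude Fisher/Haldane OR, and the PS4 decisions.
    """
    rec: dict = {}
    if "cclr" in methods:
        res = combined_lr(data, model)
        rec["lr"] = res.lr
        rec["strength"] = res.strength
        rec["lr_supporting_path"] = res.lr >= 2.08
        rec["lr_strong_path"] = res.lr >= 18.7
        rec["lr_supporting_benign"] = res.lr <= 0.48
        rec["lr_strong_benign"] = res.lr <= 0.053
    if "logistic" in methods:
        lg = logistic_or(data, adjust=("age",))
        rec["logistic_or"] = lg.or_estimate
        rec["logistic_ci_low"] = lg.ci_low
        rec["logistic_ci_high"] = lg.ci_high
        rec["logistic_p"] = lg.p_value
        rec["logistic_converged"] = lg.converged
        rec["ps4_logistic"] = ps4_criterion(lg)
    if "fisher" in methods:
        counts = ContingencySummary.from_dataset(data)
        try:
            fr = crude_or(counts)
        except ValueError as exc:
            fr = OrResult(
                np.nan, np.nan, np.nan, np.nan, "fisher",
                converged=False, flags=[str(exc)],
            )
        rec["fisher_or"] = fr.or_estimate
        rec["fisher_ci_low"] = fr.ci_low
        rec["fisher_ci_high"] = fr.ci_high
        rec["fisher_p"] = fr.p_value
        rec["fisher_haldane"] = fr.haldane_applied
        rec["ps4_fisher"] = ps4_criterion(fr)
    return rec


def replicate_lrs(
    scenario: Scenario,
    model: PenetranceModel,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """ccLR values across a scenario's replicates (fast path, ccLR only)."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    out = np.empty(scenario.replicates, dtype=float)
    for i in range(scenario.replicates):
        out[i] = combined_lr(simulate_dataset(scenario, rng), model).lr
    return out


def run_power_study(
    scenarios,
    model: PenetranceModel,
    methods=("cclr",),
) -> pd.DataFrame:
    """Estimate power/type-I error per scenario x method x criterion.

    Deterministic given each scenario's seed. Returns a tidy table with
    one row per scenario x method x criterion: the proportion of
    replicates meeting the criterion and its Monte-Carlo standard error
    ``sqrt(p (1 - p) / replicates)``.
    """
    rows = []
    for sc in scenarios:
        rng = np.random.default_rng(sc.seed)
        recs = [
            evaluate_replicate(simulate_dataset(sc, rng), model, methods)
            for _ in range(sc.replicates)
        ]
        for method in methods:
            for crit in METHOD_CRITERIA[method]:
                hits = np.fromiter((bool(r[crit]) for r in recs), dtype=bool)
                p = float(hits.mean())
                rows.append(
                    PowerResult(
                        n_per_arm=sc.n_per_arm,
                        rr=sc.rr,
                        maf=sc.maf,
                        same_age_mode=sc.same_age_mode,
                        replicates=sc.replicates,
                        seed=sc.seed,
                        method=method,
                        criterion=crit,
                        proportion=p,
                        mc_se=float(np.sqrt(p * (1 - p) / sc.replicates)),
                    )
                )
    return pd.DataFrame([asdict(r) for r in rows])
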