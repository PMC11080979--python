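"""Readers and writers.

Individual-level tables (TSV/CSV with ``sample_id, status, carrier, age``
and optional ``country``), age-group-tabulated count tables (the
calculator-style input), penetrance configurations (banded delimited
tables or constant-rate YAML/JSON shorthand), and JSON/TSV reports.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .comparators import OrResult, ps4_criterion
from .likelihood import CaseControlDataset, LikelihoodRatioResult
from .penetrance import IncidenceTable, PenetranceModel, RelativeRiskCurve

__all__ = [
    "read_individuals",
    "read_tabulated",
    "read_penetrance",
    "write_report",
    "report_dict",
    "write_individuals",
]

_NA_VALUES = ["NA", "na", "NaN", ""]

INDIVIDUAL_COLUMNS = ("sample_id", "status", "carrier", "age")
TABULATED_COLUMNS = (
    "age_group_start",
    "age_group_end",
    "cases_carriers",
    "cases_noncarriers",
    "controls_carriers",
    "controls_noncarriers",
)


def _read_table(path, dialect=None) -> pd.DataFrame:
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None and dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    if sep is None:
        return pd.read_csv(path, sep=None, engine="python",
                           na_values=_NA_VALUES, keep_default_na=True)
    return pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=True)


def _validate_binary(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() | ~vals.isin([0, 1])
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise ValueError(
            f"{path}: invalid {col!r} value {df[col][bad].iloc[0]!r} at line {line} "
            "(must be 0 or 1)"
        )
    return vals.astype(np.int8).to_numpy()


def read_individuals(path, dialect=None) -> CaseControlDataset:
    """Parse an individual-level delimited table into a dataset.

    ``age`` may be ``NA`` (unknown age, preserved as NaN); ``country`` is
    optional and becomes the stratum label. Unknown columns produce a
    warning; malformed binary fields raise with the offending line.
    """
    df = _read_table(path, dialect)
    missing = [c for c in INDIVIDUAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    known = set(INDIVIDUAL_COLUMNS) | {"country"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=2)

    status = _validate_binary(df, "status", path)
    carrier = _validate_binary(df, "carrier", path)
    age = pd.to_numeric(df["age"], errors="coerce")
    malformed = age.isna() & df["age"].notna() & (df["age"].astype(str).str.strip() != "")
    # values pandas already recognized as NA are fine; leftover junk is not
    if malformed.any():
        line = int(df.index[malformed][0]) + 2
        raise ValueError(f"{path}: non-numeric age at line {line}")
    if (age.dropna() < 0).any():
        raise ValueError(f"{path}: negative age values present")

    frame = pd.DataFrame(
        {
            "carrier": carrier,
            "status": status,
            "age": age.astype(float),
            "stratum": df["country"] if "country" in df.columns else None,
        }
    )
    return CaseControlDataset(frame, provenance=str(path))


def _representative_age(start, end, how: str) -> float:
    if how == "midpoint":
        return 0.5 * (start + end)
    if how == "lower":
        return float(start)
    if how == "upper":
        return float(end)
    raise ValueError("representative must be 'midpoint', 'lower' or 'upper'")


def read_tabulated(
    path,
    dialect=None,
    unknown_age_policy="oldest",
    representative: str = "midpoint",
) -> CaseControlDataset:
    """Expand an age-group-tabulated count table into pseudo-individuals.

    Each count cell becomes that many individuals at the age group's
    representative age (midpoint of the inclusive bounds by default).
    A row whose bounds are ``NA``/``unknown`` holds unknown-age counts and
    is routed per ``unknown_age_policy``: ``'oldest'`` assigns the oldest
    group's representative age (the conservative choice), ``'exclude'``
    drops them, a number assigns that age. Overlapping age groups within a
    country are an error.
    """
    df = _read_table(path, dialect)
    missing = [c for c in TABULATED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    has_country = "country" in df.columns

    starts = pd.to_numeric(df["age_group_start"], errors="coerce")
    ends = pd.to_numeric(df["age_group_end"], errors="coerce")
    unknown_mask = starts.isna() | ends.isna()

    count_cols = TABULATED_COLUMNS[2:]
    for col in count_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any() or (vals % 1 != 0).any():
            raise ValueError(f"{path}: column {col!r} must hold nonnegative integers")
        df[col] = vals.astype(int)

    known = df[~unknown_mask].copy()
    known["_start"] = starts[~unknown_mask]
    known["_end"] = ends[~unknown_mask]
    if (known["_end"] < known["_start"]).any():
        raise ValueError(f"{path}: age_group_end below age_group_start")

    group_key = known["country"] if has_country else pd.Series("", index=known.index)
    for label, grp in known.groupby(group_key):
        srt = grp.sort_values("_start")
        s, e = srt["_start"].to_numpy(), srt["_end"].to_numpy()
        if np.any(s[1:] <= e[:-1]):
            raise ValueError(
                f"{path}: overlapping age groups"
                + (f" in country {label!r}" if has_country else "")
            )

    rows_carrier, rows_status, rows_age, rows_stratum = [], [], [], []

    def _emit(n, carrier, status, age, stratum):
        if n > 0:
            rows_carrier.append(np.full(n, carrier, dtype=np.int8))
            rows_status.append(np.full(n, status, dtype=np.int8))
            rows_age.append(np.full(n, age, dtype=float))
            rows_stratum.extend([stratum] * n)

    cell_spec = (
        ("cases_carriers", 1, 1),
        ("cases_noncarriers", 0, 1),
        ("controls_carriers", 1, 0),
        ("controls_noncarriers", 0, 0),
    )

    for _, row in known.iterrows():
        age = _representative_age(row["_start"], row["_end"], representative)
        stratum = row["country"] if has_country else None
        for col, carrier, status in cell_spec:
            _emit(int(row[col]), carrier, status, age, stratum)

    if unknown_mask.any():
        if unknown_age_policy == "exclude":
            pass
        else:
            # per-country oldest group when countries are present
            for _, row in df[unknown_mask].iterrows():
                stratum = row["country"] if has_country else None
                if unknown_age_policy == "oldest":
                    pool = known
                    if has_country:
                        same = known[known["country"] == stratum]
                        pool = same if len(same) else known
                    if not len(pool):
                        raise ValueError(
                            f"{path}: unknown-age row but no age groups to assign from"
                        )
                    oldest = pool.loc[pool["_end"].idxmax()]
                    age = _representative_age(
                        oldest["_start"], oldest["_end"], representative
                    )
                else:
                    age = float(unknown_age_policy)
                for col, carrier, status in cell_spec:
                    _emit(int(row[col]), carrier, status, age, stratum)

    if not rows_carrier:
        raise ValueError(f"{path}: no individuals after expansion")
    frame = pd.DataFrame(
        {
            "carrier": np.concatenate(rows_carrier),
            "status": np.concatenate(rows_status),
            "age": np.concatenate(rows_age),
            "stratum": rows_stratum,
        }
    )
    return CaseControlDataset(frame, provenance=str(path))


# ---------------------------------------------------------------------------
# Penetrance configuration
# ---------------------------------------------------------------------------


def _model_from_bands(df: pd.DataFrame, age_range) -> PenetranceModel:
    required = ("age_start", "age_end", "baseline_rate", "rr")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"penetrance table missing column(s) {missing}")
    df = df.sort_values("age_start").reset_index(drop=True)
    starts = df["age_start"].to_numpy(float)
    ends = df["age_end"].to_numpy(float)
    if not np.allclose(starts[1:], ends[:-1]):
        raise ValueError("penetrance bands must be contiguous (age_start == previous age_end)")
    edges = np.concatenate([starts, ends[-1:]])
    inc = IncidenceTable(edges, df["baseline_rate"].to_numpy(float))
    rrc = RelativeRiskCurve.from_rr(edges, df["rr"].to_numpy(float))
    return PenetranceModel(inc, rrc, age_range)


def read_penetrance(path, age_range=None) -> PenetranceModel:
    """Load a penetrance model from a banded table or a config file.

    Delimited tables need ``age_start, age_end, baseline_rate, rr`` (one
    row per band). YAML/JSON configs either carry a ``bands`` list of the
    same fields or the constant shorthand ``{baseline_rate, rr}``; an
    optional ``age_range`` key overrides the default [21, 80].
    """
    p = Path(path)
    if p.suffix.lower() in {".yaml", ".yml", ".json"}:
        cfg = yaml.safe_load(p.read_text())
        if not isinstance(cfg, dict):
            raise ValueError(f"{path}: penetrance config must be a mapping")
        ar = tuple(cfg.get("age_range", age_range or (21.0, 80.0)))
        if "bands" in cfg:
            return _model_from_bands(pd.DataFrame(cfg["bands"]), ar)
        if "baseline_rate" in cfg and "rr" in cfg:
            return PenetranceModel.constant(float(cfg["baseline_rate"]),
                                            float(cfg["rr"]), ar)
        raise ValueError(f"{path}: config needs 'bands' or 'baseline_rate'+'rr'")
    return _model_from_bands(_read_table(path), age_range or (21.0, 80.0))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _fmt_lr(x: float) -> str:
    if 0.01 <= x < 1e7:
        return f"{x:.2f}"
    return f"{x:.3g}"


def report_dict(result) -> dict:
    """Stable JSON-ready representation of a result object."""
    if isinstance(result, LikelihoodRatioResult):
        return {
            "lr": result.lr,
            "log_lr": result.log_lr,
            "k": result.k_total,
            "n": result.n_total,
            "strength": result.strength,
            "flags": list(result.flags),
            "per_stratum": {
                lab: {"lr": s.lr, "k": s.k, "n": s.n, "flags": list(s.flags)}
                for lab, s in result.per_stratum.items()
            },
        }
    if isinstance(result, OrResult):
        def _num(x):  # JSON has no inf/nan
            return float(x) if np.isfinite(x) else None

        return {
            "method": result.method,
            "or": _num(result.or_estimate),
            "ci_low": _num(result.ci_low),
            "ci_high": _num(result.ci_high),
            "p": _num(result.p_value),
            "haldane_applied": result.haldane_applied,
            "converged": result.converged,
            "ps4": ps4_criterion(result),
            "flags": list(result.flags),
        }
    raise TypeError(f"no report representation for {type(result).__name__}")


def _lr_result_rows(result: LikelihoodRatioResult):
    yield ("overall", _fmt_lr(result.lr), result.k_total, result.n_total,
           result.strength, ";".join(result.flags))
    for lab, s in result.per_stratum.items():
        yield (lab, _fmt_lr(s.lr), s.k, s.n, "", ";".join(s.flags))


def write_report(result, path, format: str = "json") -> None:
    """Write a result (LR, OR, or a tidy power DataFrame) to disk.

    JSON keeps full precision; TSV prints LRs Table-style with at least
    two decimal places.
    """
    path = Path(path)
    if isinstance(result, pd.DataFrame):
        if format == "json":
            path.write_text(json.dumps(result.to_dict(orient="records"), indent=2) + "\n")
        elif format == "tsv":
            result.to_csv(path, sep="\t", index=False)
        else:
            raise ValueError("format must be 'json' or 'tsv'")
        return
    d = report_dict(result)
    if format == "json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    elif format == "tsv":
        if isinstance(result, LikelihoodRatioResult):
            header = "stratum\tlr\tk\tn\tstrength\tflags\n"
            lines = ["\t".join(str(x) for x in row) for row in _lr_result_rows(result)]
            path.write_text(header + "\n".join(lines) + "\n")
        else:
            keys = list(d.keys())[:-1]  # flags last, joined
            header = "\t".join(keys + ["flags"]) + "\n"
            vals = [str(d[k]) for k in keys] + [";".join(d["flags"])]
            path.write_text(header + "\t".join(vals) + "\n")
    else:
        raise ValueError("format must be 'json' or 'tsv'")


def write_individuals(data: CaseControlDataset, path) -> None:
    """Write a dataset as an individual-level TSV (round-trips with read_individuals)."""
    f = data.frame
    out = pd.DataFrame(
        {
            "sample_id": [f"s{i + 1}" for i in range(len(f))],
            "status": f["status"].to_numpy(),
            "carrier": f["carrier"].to_numpy(),
            "age": f["age"].to_numpy(),
        }
    )
    if f["stratum"].notna().any():
        out["country"] = f["stratum"].to_numpy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
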