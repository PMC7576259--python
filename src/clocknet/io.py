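"""Delimited-text readers and writers for every on-disk artifact.

The canonical layout follows GEO series-matrix conventions: features (CpGs
or genes) in rows with a leading identifier column, samples in columns;
tab-delimited by default with comma accepted.  Missing beta values are
encoded as ``NA``.  Meta-clock models serialize to a self-describing JSON
text file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clocks import ClockDefinition
from .metaclock import MetaClockModel

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_expression_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_clock_definitions",
    "write_clock_definitions",
    "read_partition",
    "write_partition",
    "read_metaclock_model",
    "write_metaclock_model",
    "write_report",
]

_BETA_TOL = 1e-9


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return "\t"


def _read_matrix(path, dialect: str, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#",
                     na_values=["NA"], keep_default_na=True)
    if dialect == "samples":  # samples in rows -> transpose to features-in-rows
        df = df.T
    elif dialect != "features":
        raise ValueError(f"unknown dialect {dialect!r}")
    for axis, what in ((df.index, "feature"), (df.columns, "sample")):
        if axis.duplicated().any():
            dup = axis[axis.duplicated()].tolist()
            raise ValueError(f"duplicate {what} identifier(s): {dup[:5]}")
    df.index.name = None
    df.columns.name = None
    bad = df.map(lambda v: isinstance(v, str)).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return df.astype(float)


def read_beta_matrix(path, dialect: str = "features", sep: str | None = None) -> pd.DataFrame:
    """Read a CpG x sample beta matrix.

    ``dialect="features"`` (default, GEO-style) expects CpGs in rows;
    ``dialect="samples"`` expects samples in rows and transposes.  Values
    outside [0, 1] by more than 1e-9 are an error; values outside by at
    most rounding error are clamped.  ``NA`` cells become NaN.
    """
    df = _read_matrix(path, dialect, sep)
    vals = df.to_numpy()
    with np.errstate(invalid="ignore"):
        out_of_range = (vals < -_BETA_TOL) | (vals > 1 + _BETA_TOL)
    if np.nansum(out_of_range):
        i, j = np.argwhere(out_of_range & ~np.isnan(vals))[0]
        raise ValueError(
            f"beta value {vals[i, j]} out of [0, 1] at "
            f"({df.index[i]!r}, {df.columns[j]!r})"
        )
    return df.clip(lower=0.0, upper=1.0)


def read_expression_matrix(path, dialect: str = "features", sep: str | None = None) -> pd.DataFrame:
    """Read a gene x sample expression matrix (finite values, any scale)."""
    return _read_matrix(path, dialect, sep)


def write_beta_matrix(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, na_rep="NA", index_label="id",
              float_format="%.17g")


def read_sample_table(path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample id(s): {dup[:5]}")
    if "age" in df.columns and (df["age"].dropna() < 0).any():
        raise ValueError("negative age")
    if "event" in df.columns:
        ev = df["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("event must be 0/1")
        if "time" not in df.columns or df.loc[ev.index, "time"].isna().any():
            raise ValueError("time must be present wherever event is present")
        if (df.loc[ev.index, "time"] <= 0).any():
            raise ValueError("follow-up time must be > 0")
    return df


def write_sample_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, na_rep="NA", index_label="sample_id",
              float_format="%.17g")


def read_clock_definitions(path, sep: str | None = None) -> list[ClockDefinition]:
    """Read clock coefficient files.

    Format: metadata lines ``#clock<sep>name<sep>intercept<sep>calibration
    [<sep>adult_age]`` followed by a delimited table with columns
    (clock, cpg, weight).  CpG order is preserved as read; a clock present
    in the table but lacking a metadata line is an error, as is a
    duplicated CpG within one clock or a horvath calibration without
    adult_age.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = sep or _sniff_sep(path)
    meta: dict[str, tuple[float, str, float | None]] = {}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#clock"):
                parts = line.split(sep)
                if len(parts) < 4:
                    raise ValueError(f"malformed metadata line: {line!r}")
                name, intercept, calibration = parts[1], float(parts[2]), parts[3]
                adult_age = float(parts[4]) if len(parts) > 4 and parts[4] != "" else None
                if calibration == "horvath" and adult_age is None:
                    raise ValueError(
                        f"clock {name!r}: horvath calibration requires adult_age"
                    )
                meta[name] = (intercept, calibration, adult_age)
            elif line.startswith("#") or not line.strip():
                continue
            else:
                rows.append(line)
    if not rows:
        raise ValueError("no coefficient rows found")
    header = rows[0].split(sep)
    try:
        ic, jc, kc = (header.index(c) for c in ("clock", "cpg", "weight"))
    except ValueError as exc:
        raise ValueError("coefficient table needs columns clock, cpg, weight") from exc
    weights: dict[str, dict[str, float]] = {}
    for line in rows[1:]:
        parts = line.split(sep)
        name, cpg, w = parts[ic], parts[jc], float(parts[kc])
        d = weights.setdefault(name, {})
        if cpg in d:
            raise ValueError(f"clock {name!r}: duplicate CpG {cpg!r}")
        d[cpg] = w
    clocks = []
    for name, w in weights.items():
        if name not in meta:
            raise ValueError(f"clock {name!r} has coefficients but no metadata line")
        intercept, calibration, adult_age = meta[name]
        kwargs = {} if adult_age is None else {"adult_age": adult_age}
        clocks.append(
            ClockDefinition(name=name, intercept=intercept, weights=w,
                            calibration=calibration, **kwargs)
        )
    return clocks


def write_clock_definitions(clocks: list[ClockDefinition], path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for c in clocks:
            fh.write(sep.join(
                ["#clock", c.name, repr(c.intercept), c.calibration,
                 repr(c.adult_age)]
            ) + "\n")
        fh.write(sep.join(["clock", "cpg", "weight"]) + "\n")
        for c in clocks:
            for cpg, w in c.weights.items():
                fh.write(sep.join([c.name, cpg, repr(float(w))]) + "\n")


def read_partition(path, sep: str | None = None) -> pd.Series:
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.iloc[:, 0].rename("module")


def write_partition(partition: pd.Series, path, sep: str = "\t") -> None:
    partition.rename("module").to_csv(path, sep=sep, index_label="feature")


def write_metaclock_model(model: MetaClockModel, path) -> None:
    """Self-describing JSON serialization of a trained meta-clock."""
    payload = {
        "format": "clocknet-metaclock",
        "version": 1,
        "alpha": model.alpha,
        "lambda": model.lam,
        "mode": model.mode,
        "training": {"n": model.n, "events": model.events,
                     "folds": model.folds, "seed": model.seed},
        "features": [
            {"clock": f[0], "module": f[1], "mean": m, "sd": s,
             "coefficient": model.coefficients.get(f, 0.0)}
            for f, m, s in zip(model.features, model.means, model.sds)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_metaclock_model(path) -> MetaClockModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "clocknet-metaclock":
        raise ValueError("not a clocknet meta-clock model file")
    feats = [(f["clock"], f["module"]) for f in payload["features"]]
    return MetaClockModel(
        features=feats,
        means=[f["mean"] for f in payload["features"]],
        sds=[f["sd"] for f in payload["features"]],
        coefficients={
            (f["clock"], f["module"]): f["coefficient"]
            for f in payload["features"] if f["coefficient"] != 0.0
        },
        alpha=payload["alpha"],
        lam=payload["lambda"],
        n=payload["training"]["n"],
        events=payload["training"]["events"],
        folds=payload["training"]["folds"],
        seed=payload["training"]["seed"],
        mode=payload.get("mode", "published"),
    )


def write_report(results, path, sep: str = "\t") -> None:
    """Write analysis results as machine-readable table(s) plus a summary.

    ``results`` may be a DataFrame or a mapping of section name ->
    DataFrame (or dataclass-like records).  Output is deterministic for
    identical inputs: sections in input order, stable float formatting.
    """
    if isinstance(results, pd.DataFrame):
        results = {"results": results}
    path = Path(path)
    lines: list[str] = []
    for name, table in results.items():
        if not isinstance(table, pd.DataFrame):
            table = pd.DataFrame(table)
        lines.append(f"## {name}")
        lines.append(f"# rows={len(table)}")
        lines.append(table.to_csv(sep=sep, index=False, float_format="%.10g",
                                  na_rep="NA").rstrip("\n"))
        lines.append("")
    path.write_text("\n".join(lines) + "\n")
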