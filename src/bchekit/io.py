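"""CSV/JSON formats and run configuration.

The curve CSV dialect is deliberately strict: comma-separated, UTF-8, dot
decimals, mandatory header with exactly the columns
``label, substrate, S_uM, rate_U_per_mL, replicate`` — unknown or missing
columns are rejected by name, malformed rows by line number.  Every JSON
artifact embeds the run configuration and package version, and tags each
numeric field with its unit (µM/mM confusion being the classic trap in
this assay family).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .fitting import FitResult, RateCurve
from .phenotype import InhibitionAssay, PhenotypeCall

__all__ = [
    "CURVE_COLUMNS",
    "CurveFormatError",
    "RunConfig",
    "read_curve_csv",
    "write_curve_csv",
    "read_inhibition_csv",
    "write_inhibition_csv",
    "fit_result_to_json",
    "phenotype_call_to_json",
]

CURVE_COLUMNS = ("label", "substrate", "S_uM", "rate_U_per_mL", "replicate")
INHIBITION_COLUMNS = (
    "inhibitor",
    "inhibitor_conc_uM",
    "substrate",
    "substrate_conc_uM",
    "v0_U_per_mL",
    "vi_U_per_mL",
)


class CurveFormatError(ValueError):
    """A curve/assay table violates the CSV contract."""


@dataclass(frozen=True)
class RunConfig:
    """Defaulted analysis settings, embedded in every output for provenance."""

    alpha: float = 0.05
    noise_cv: float = 0.03
    bootstrap_B: int = 500
    seed: int = 0
    reference_group: str = "infants"
    dn_thresholds: dict = field(
        default_factory=lambda: {"usual": 70.0, "heterozygous": 40.0, "atypical": 30.0}
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_columns(df: pd.DataFrame, expected: tuple[str, ...], path) -> None:
    got = tuple(df.columns)
    unknown = [c for c in got if c not in expected]
    missing = [c for c in expected if c not in got]
    if unknown:
        raise CurveFormatError(f"{path}: unknown column(s) {unknown}")
    if missing:
        raise CurveFormatError(f"{path}: missing column(s) {missing}")


def read_curve_csv(path) -> RateCurve:
    """Parse a saturation-curve CSV into a :class:`RateCurve` (row order
    preserved; S in µM, rates in U/mL)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise CurveFormatError(f"{path}: empty file") from exc
    if df.empty:
        raise CurveFormatError(f"{path}: no data rows")
    _check_columns(df, CURVE_COLUMNS, path)

    s_vals, v_vals, reps = [], [], []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            s = float(row["S_uM"])
            v = float(row["rate_U_per_mL"])
            rep = int(row["replicate"])
        except ValueError as exc:
            raise CurveFormatError(f"{path}: line {line_no}: {exc}") from exc
        if s <= 0:
            raise CurveFormatError(
                f"{path}: line {line_no}: S_uM must be positive, got {s:g}"
            )
        if v < 0:
            raise CurveFormatError(
                f"{path}: line {line_no}: rate_U_per_mL must be nonnegative"
            )
        s_vals.append(s)
        v_vals.append(v)
        reps.append(rep)
    label = str(df["label"].iloc[0]) if len(df) else ""
    return RateCurve(s_um=s_vals, v=v_vals, replicate=reps, label=label)


def write_curve_csv(curve: RateCurve, path, substrate: str = "BTC") -> None:
    df = pd.DataFrame(
        {
            "label": curve.label,
            "substrate": substrate,
            "S_uM": curve.s_um,
            "rate_U_per_mL": curve.v,
            "replicate": curve.replicate,
        }
    )
    df.to_csv(path, index=False)


def write_inhibition_csv(assays: list[InhibitionAssay], path) -> None:
    rows = [
        {
            "inhibitor": a.inhibitor.value,
            "inhibitor_conc_uM": a.inhibitor_conc_um,
            "substrate": a.substrate,
            "substrate_conc_uM": a.substrate_conc_um,
            "v0_U_per_mL": a.v0,
            "vi_U_per_mL": a.vi,
        }
        for a in assays
    ]
    pd.DataFrame(rows, columns=INHIBITION_COLUMNS).to_csv(path, index=False)


def read_inhibition_csv(path) -> list[InhibitionAssay]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CurveFormatError(f"{path}: empty file") from exc
    _check_columns(df, INHIBITION_COLUMNS, path)
    assays = []
    for idx, row in df.iterrows():
        try:
            assays.append(
                InhibitionAssay(
                    inhibitor=row["inhibitor"],
                    inhibitor_conc_um=float(row["inhibitor_conc_uM"]),
                    substrate_conc_um=float(row["substrate_conc_uM"]),
                    v0=float(row["v0_U_per_mL"]),
                    vi=float(row["vi_U_per_mL"]),
                )
            )
        except ValueError as exc:
            raise CurveFormatError(f"{path}: line {idx + 2}: {exc}") from exc
    return assays


def _envelope(payload: dict, config: RunConfig | None) -> dict:
    return {
        "package": "bchekit",
        "version": __version__,
        "config": (config or RunConfig()).to_dict(),
        **payload,
    }


def fit_result_to_json(result: FitResult, path=None,
                       config: RunConfig | None = None) -> str:
    doc = _envelope({"fit": result.to_dict()}, config)
    text = json.dumps(doc, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def phenotype_call_to_json(call: PhenotypeCall, path=None,
                           config: RunConfig | None = None) -> str:
    doc = _envelope({"phenotype": call.to_dict()}, config)
    text = json.dumps(doc, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text
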