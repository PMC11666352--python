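"""Measured enzyme properties: censoring-aware tables, schemas, preprocessing.

The package ships transcriptions of the study's two experimental tables as TSV
fixtures: multiparametric measurements of 46 Taq polymerase mutants plus the
wild type across three design rounds (reverse-transcriptase ``dCq`` against
four cDNA lengths, relative rate constant, fidelity, dT/dU rate, LNA delays,
K_d, catalytic constants, temperature optimum, and hot-start blocking levels).
Censored entries are kept as such: ``N/A`` marks a value below the detection
limit and ``>40``-style entries carry only a lower bound.

Targets are preprocessed for regression by an optional log transform followed
by z-scaling; the fitted ``TransformParams`` invert the mapping exactly, so
predictive densities can be reported on the original measurement scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Censor = Literal["exact", "above", "below_detection"]

#: numeric property columns understood by the loaders
KNOWN_PROPERTIES = (
    "rt90", "rt116", "rt201", "rt526", "k_rel", "fidelity", "dTdU_rate",
    "t_opt", "lna1_delay", "lna2_delay", "lna3_delay", "kd",
    "kcat_dT", "kcat_dU", "pcr_efficiency",
    "antibody_block_score", "aptamer_block_score",
)
BLOCKING_COLUMNS = ("antibody_blocking", "aptamer_blocking")
METADATA_COLUMNS = ("variant", "round", "literature_selected", "literature_data")

BLOCKING_LOSS_SCORE = {"Strong": 0.0, "Weak": 0.5, "Absent": 1.0}

#: lower values are better for dCq-type and cost-type properties
DIRECTION_OF_MERIT = {
    "rt90": "lower", "rt116": "lower", "rt201": "lower", "rt526": "lower",
    "dTdU_rate": "lower", "kd": "lower", "lna1_delay": "lower",
    "lna2_delay": "lower", "lna3_delay": "lower",
    "antibody_block_score": "lower", "aptamer_block_score": "lower",
    "k_rel": "higher", "fidelity": "higher", "kcat_dT": "higher",
    "kcat_dU": "higher", "pcr_efficiency": "higher", "t_opt": "higher",
}


class TableError(ValueError):
    """Malformed property table."""


@dataclass(frozen=True)
class Measurement:
    """A possibly censored measurement.

    ``above`` carries the printed bound in ``value``; ``below_detection``
    carries no value at all.
    """

    value: float | None
    censor: Censor = "exact"

    def __post_init__(self) -> None:
        if self.censor == "below_detection" and self.value is not None:
            raise ValueError("below_detection carries no value")
        if self.censor in ("exact", "above") and self.value is None:
            raise ValueError(f"{self.censor} measurement requires a value")


@dataclass(frozen=True)
class PropertySchema:
    name: str
    transform: Literal["log", "identity"] = "identity"
    direction_of_merit: Literal["higher", "lower"] = "higher"
    training_role: Literal["train", "monitor"] = "train"
    units: str = ""


def default_schemas() -> list[PropertySchema]:
    """Per-property modeling schema used for the study's design rounds.

    Strictly positive right-skewed properties are log-transformed; dCq-type
    differences stay on the identity scale. Short-template RT activities,
    the rate constant ratio, fidelity, PCR efficiency, dT/dU, catalytic
    constants, and the two blocking scores are training targets; the long
    templates and the LNA-3 delay are monitored only.
    """
    d = DIRECTION_OF_MERIT
    return [
        PropertySchema("rt90", "identity", d["rt90"], "train", "dCq"),
        PropertySchema("rt116", "identity", d["rt116"], "train", "dCq"),
        PropertySchema("rt201", "identity", d["rt201"], "monitor", "dCq"),
        PropertySchema("rt526", "identity", d["rt526"], "monitor", "dCq"),
        PropertySchema("k_rel", "log", d["k_rel"], "train", "ratio to WT"),
        PropertySchema("fidelity", "log", d["fidelity"], "train", "nt/error"),
        PropertySchema("dTdU_rate", "log", d["dTdU_rate"], "train", "ratio"),
        PropertySchema("pcr_efficiency", "identity", d["pcr_efficiency"], "train", "per cycle"),
        PropertySchema("kcat_dT", "log", d["kcat_dT"], "train", "1/s"),
        PropertySchema("kcat_dU", "log", d["kcat_dU"], "train", "1/s"),
        PropertySchema("kd", "log", d["kd"], "monitor", "nM"),
        PropertySchema("lna3_delay", "log", d["lna3_delay"], "monitor", "fold"),
        PropertySchema("antibody_block_score", "identity", "lower", "train", "loss score"),
        PropertySchema("aptamer_block_score", "identity", "lower", "train", "loss score"),
    ]


def parse_cell(text: str) -> Measurement:
    """Parse one table cell: a number (comma thousands separators allowed),
    ``N/A`` (below detection) or ``>bound`` (above the quantifiable range)."""
    token = text.strip().replace("−", "-")  # typeset minus
    if token in ("N/A", "NA", ""):
        return Measurement(None, "below_detection")
    if token.startswith(">"):
        return Measurement(float(token[1:].replace(",", "")), "above")
    return Measurement(float(token.replace(",", "")), "exact")


class PropertyTable:
    """Enzymes x properties with censoring flags and blocking levels.

    ``values`` holds numbers (the printed bound for ``above`` cells, NaN for
    ``below_detection``); ``censor`` holds the matching flag per cell;
    ``blocking`` holds raw categorical levels; ``rounds`` the design round
    label per enzyme. Row index is the variant name ("WT" for the wild type).
    """

    def __init__(self, values: pd.DataFrame, censor: pd.DataFrame,
                 blocking: pd.DataFrame, rounds: pd.Series,
                 metadata: pd.DataFrame | None = None) -> None:
        self.values = values
        self.censor = censor
        self.blocking = blocking
        self.rounds = rounds
        self.metadata = metadata if metadata is not None else pd.DataFrame(index=values.index)

    @property
    def properties(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)

    def exact_values(self, column: str) -> pd.Series:
        """Values of exactly measured cells only (censored cells dropped)."""
        mask = self.censor[column] == "exact"
        return self.values.loc[mask, column]

    def measurement(self, row: str, column: str) -> Measurement:
        censor = self.censor.at[row, column]
        value = self.values.at[row, column]
        return Measurement(None if censor == "below_detection" else float(value), censor)

    def with_blocking_scores(self) -> "PropertyTable":
        """Return a copy whose blocking levels are also present as numeric
        loss-score columns (Strong=0, Weak=0.5, Absent=1)."""
        values = self.values.copy()
        censor = self.censor.copy()
        for raw, col in (("antibody_blocking", "antibody_block_score"),
                         ("aptamer_blocking", "aptamer_block_score")):
            if raw in self.blocking.columns:
                scores = [encode_blocking(v) if isinstance(v, str) and v in BLOCKING_LOSS_SCORE
                          else np.nan for v in self.blocking[raw]]
                values[col] = scores
                censor[col] = ["exact" if not math.isnan(s) else "below_detection"
                               for s in scores]
        return PropertyTable(values, censor, self.blocking, self.rounds, self.metadata)

    def concat(self, other: "PropertyTable") -> "PropertyTable":
        return PropertyTable(
            pd.concat([self.values, other.values]),
            pd.concat([self.censor, other.censor]),
            pd.concat([self.blocking, other.blocking]),
            pd.concat([self.rounds, other.rounds]),
            pd.concat([self.metadata, other.metadata]),
        )


def load_property_table(path: str | Path) -> PropertyTable:
    """Load a TSV property table (columns: ``variant``, ``round``, properties,
    blocking levels). Censored syntax: ``N/A`` and ``>``+number."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.empty or "variant" not in raw.columns:
        raise TableError(f"{path}: empty table or missing 'variant' column")
    unknown = [c for c in raw.columns
               if c not in KNOWN_PROPERTIES + BLOCKING_COLUMNS + METADATA_COLUMNS]
    if unknown:
        raise TableError(f"{path}: unknown columns {unknown}")
    raw = raw.set_index("variant")

    prop_cols = [c for c in raw.columns if c in KNOWN_PROPERTIES]
    values = pd.DataFrame(index=raw.index, columns=prop_cols, dtype=float)
    censor = pd.DataFrame("exact", index=raw.index, columns=prop_cols)
    for col in prop_cols:
        for row, cell in raw[col].items():
            try:
                m = parse_cell(cell)
            except ValueError as exc:
                raise TableError(f"{path}: unparseable cell {cell!r} "
                                 f"(row {row!r}, column {col!r})") from exc
            values.at[row, col] = np.nan if m.value is None else m.value
            censor.at[row, col] = m.censor

    blocking = raw[[c for c in BLOCKING_COLUMNS if c in raw.columns]].copy()
    rounds = raw["round"] if "round" in raw.columns else pd.Series("I", index=raw.index)
    meta_cols = [c for c in ("literature_selected", "literature_data") if c in raw.columns]
    return PropertyTable(values, censor, blocking, rounds, raw[meta_cols].copy())


def load_study_tables() -> PropertyTable:
    """The packaged transcriptions of the study's Tables 1 and 2, combined
    (19 round-I enzymes incl. WT + 28 round-II/III enzymes)."""
    data = Path(__file__).parent / "data"
    t1 = load_property_table(data / "table1.tsv")
    t2 = load_property_table(data / "table2.tsv")
    return t1.concat(t2)


def write_property_table(table: PropertyTable, path: str | Path) -> None:
    """Write a PropertyTable in the same TSV dialect the loader reads
    (``N/A`` for below-detection cells, ``>``+bound for censored-above)."""
    cols = list(table.values.columns)
    bcols = list(table.blocking.columns)
    with open(path, "w") as fh:
        fh.write("\t".join(["variant", "round", *cols, *bcols]) + "\n")
        for row in table.values.index:
            cells = []
            for col in cols:
                c = table.censor.at[row, col]
                if c == "below_detection":
                    cells.append("N/A")
                elif c == "above":
                    cells.append(f">{table.values.at[row, col]:g}")
                else:
                    cells.append(f"{table.values.at[row, col]:.10g}")
            blk = [str(table.blocking.at[row, b]) for b in bcols]
            fh.write("\t".join([row, str(table.rounds.at[row]), *cells, *blk]) + "\n")


def encode_blocking(level: str) -> float:
    """Ordinal blocking-loss score: Strong -> 0.0, Weak -> 0.5, Absent -> 1.0.

    Higher score = more complete loss of the hot-start blocking.
    """
    try:
        return BLOCKING_LOSS_SCORE[level]
    except KeyError:
        raise ValueError(f"unknown blocking level {level!r}") from None


@dataclass
class TransformParams:
    """Invertible per-target preprocessing: optional log, then z-scaling."""

    transform: Literal["log", "identity"]
    mean: float
    sd: float

    def forward(self, y: np.ndarray | float) -> np.ndarray | float:
        y = np.log(y) if self.transform == "log" else np.asarray(y, dtype=float)
        return (y - self.mean) / self.sd

    def inverse(self, z: np.ndarray | float) -> np.ndarray | float:
        y = np.asarray(z, dtype=float) * self.sd + self.mean
        return np.exp(y) if self.transform == "log" else y


def preprocess_targets(table: PropertyTable, schemas: Sequence[PropertySchema],
                       ) -> tuple[pd.DataFrame, dict[str, TransformParams]]:
    """Modeling-scale target matrix and exact inverse transforms.

    Censored cells are excluded from the fit set (NaN in the output); each
    retained column is log-transformed where the schema says so, then scaled
    to zero mean and unit sd over its exact cells.
    """
    out = {}
    params: dict[str, TransformParams] = {}
    for schema in schemas:
        if schema.name not in table.values.columns:
            continue
        exact = table.exact_values(schema.name)
        if len(exact) < 2:
            raise TableError(f"column {schema.name!r}: fewer than 2 exact measurements")
        y = exact.to_numpy(dtype=float)
        if schema.transform == "log":
            if np.any(y <= 0):
                raise TableError(f"column {schema.name!r}: log of non-positive value")
            y = np.log(y)
        mean, sd = float(np.mean(y)), float(np.std(y))
        if sd == 0:
            raise TableError(f"column {schema.name!r}: zero variance")
        p = TransformParams(schema.transform, mean, sd)
        col = pd.Series(np.nan, index=table.values.index)
        col[exact.index] = p.forward(exact.to_numpy(dtype=float))
        out[schema.name] = col
        params[schema.name] = p
    return pd.DataFrame(out), params


def correlation_matrix(table: PropertyTable, method: str = "spearman",
                       min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete correlation matrix over exactly measured cells.

    Cells with fewer than ``min_pairs`` complete pairs are reported missing.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    exact = table.values.where(table.censor == "exact")
    return exact.corr(method=method, min_periods=min_pairs)


def squared_pearson(table: PropertyTable, col_a: str, col_b: str) -> float:
    """r^2 between two columns over rows where both are exactly measured."""
    a = table.values[col_a].where(table.censor[col_a] == "exact")
    b = table.values[col_b].where(table.censor[col_b] == "exact")
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise TableError(f"fewer than 3 complete pairs for {col_a}/{col_b}")
    if a[ok].nunique() == 1 or b[ok].nunique() == 1:
        raise TableError("constant column")
    r, _ = stats.pearsonr(a[ok], b[ok])
    return float(r ** 2)


def count_exceeding_reference(table: PropertyTable, properties: Sequence[str],
                              reference_row: str = "WT",
                              direction: str | dict[str, str] | None = None) -> int:
    """Rows strictly better than the reference in ALL listed properties.

    ``direction`` is "higher"/"lower" (applied to every property), a
    per-property mapping, or None to use each property's direction of merit.
    Censored cells never count as better.
    """
    if reference_row not in table.values.index:
        raise TableError(f"reference row {reference_row!r} not in table")
    for p in properties:
        if p not in table.values.columns:
            raise TableError(f"unknown property {p!r}")

    def dir_for(p: str) -> str:
        if direction is None:
            return DIRECTION_OF_MERIT[p]
        if isinstance(direction, str):
            return direction
        return direction[p]

    count = 0
    for row in table.values.index:
        if row == reference_row:
            continue
        better_all = True
        for p in properties:
            ref = table.measurement(reference_row, p)
            m = table.measurement(row, p)
            if m.censor == "below_detection" or ref.value is None:
                better_all = False
                break
            # 'above' bounds are compared at the bound (conservative for
            # lower-is-better; for higher-is-better the truth is at least
            # as good as the bound implies).
            if dir_for(p) == "lower":
                better = m.value < ref.value and m.censor != "above"
            else:
                better = m.value > ref.value
            if not better:
                better_all = False
                break
        count += better_all
    return count


def count_detectable(table: PropertyTable, prop: str) -> int:
    """Number of rows whose measurement of ``prop`` is exact (detectable)."""
    if prop not in table.censor.columns:
        raise TableError(f"unknown property {prop!r}")
    return int((table.censor[prop] == "exact").sum())
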