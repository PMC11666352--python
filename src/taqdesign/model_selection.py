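"""Low-N model benchmarking: repeated small-train sampling, rank metrics.

The evaluation mirrors the practical design setting: a model only ever sees a
small training set (18 measured variants in the first round of the campaign),
and what matters is whether its top-ranked predictions are truly better than
the wild type. Accordingly the protocol repeatedly samples small training
sets, fits, and scores the held-out remainder with Spearman rank correlation
and Top-k hit rates (fraction of the k best-predicted variants whose true
value beats the wild type).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import ProteinSequence, VariantError, parse_variant


@dataclass(frozen=True)
class EvalProtocol:
    train_size: int = 18
    repetitions: int = 20
    seed: int = 0
    k_list: tuple[int, ...] = (4, 8, 16, 24)


@dataclass
class MetricDistribution:
    name: str
    values: np.ndarray

    @property
    def median(self) -> float:
        ok = self.values[np.isfinite(self.values)]
        return float(np.median(ok)) if len(ok) else float("nan")

    @property
    def iqr(self) -> tuple[float, float]:
        ok = self.values[np.isfinite(self.values)]
        if not len(ok):
            return (float("nan"), float("nan"))
        return (float(np.percentile(ok, 25)), float(np.percentile(ok, 75)))


def spearman_rank(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (undefined, not fabricated) when either vector is constant.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or len(pred) < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.all(pred == pred[0]) or np.all(truth == truth[0]):
        return float("nan")
    rho, _ = stats.spearmanr(pred, truth)
    return float(rho)


def topk_hit_rate(pred: Sequence[float], truth: Sequence[float],
                  wt_truth: float, k: int, direction: str = "higher",
                  names: Sequence[str] | None = None) -> float:
    """Fraction of the k best-predicted items whose TRUE value beats the WT.

    ``direction`` is the direction of merit for the property. Prediction ties
    are broken deterministically by name (lexicographic) when names are given,
    else by input order.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(pred):
        raise ValueError(f"k={k} exceeds {len(pred)} items")
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    merit = pred if direction == "higher" else -pred
    tiebreak = np.asarray(names, dtype=str) if names is not None \
        else np.arange(len(pred)).astype(str)
    order = sorted(range(len(pred)), key=lambda i: (-merit[i], tiebreak[i]))
    top = order[:k]
    if direction == "higher":
        hits = sum(truth[i] > wt_truth for i in top)
    else:
        hits = sum(truth[i] < wt_truth for i in top)
    return hits / k


ModelFactory = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


def run_protocol(X: np.ndarray, y: np.ndarray, wt_truth: float,
                 model_factory: ModelFactory, protocol: EvalProtocol,
                 names: Sequence[str] | None = None,
                 direction: str = "higher") -> dict[str, MetricDistribution]:
    """Repeated random small-train evaluation.

    Per repetition: draw ``train_size`` items without replacement (seeded,
    index-free: sampling operates on the canonical name order so dataset row
    order does not matter), fit via ``model_factory``, score Spearman and all
    Top-k metrics on the remainder. Model failures are recorded as NaN and the
    run continues.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if protocol.train_size >= n:
        raise ValueError("train_size must be smaller than the dataset")
    if names is None:
        names = [str(i) for i in range(n)]
    canon = sorted(range(n), key=lambda i: names[i])

    metric_names = ["spearman"] + [f"top{k}" for k in protocol.k_list
                                   if k <= n - protocol.train_size]
    values = {m: np.full(protocol.repetitions, np.nan) for m in metric_names}
    rng = np.random.default_rng(protocol.seed)
    for rep in range(protocol.repetitions):
        pick = rng.choice(n, size=protocol.train_size, replace=False)
        train = [canon[i] for i in pick]
        test = [i for i in canon if i not in set(train)]
        try:
            predictor = model_factory(X[train], y[train])
            pred = np.asarray(predictor(X[test]), dtype=float)
        except Exception:
            continue
        values["spearman"][rep] = spearman_rank(pred, y[test])
        for k in protocol.k_list:
            if k <= len(test):
                values[f"top{k}"][rep] = topk_hit_rate(
                    pred, y[test], wt_truth, k, direction,
                    [names[i] for i in test])
    return {m: MetricDistribution(m, v) for m, v in values.items()}


def read_dms_table(path: str | Path, reference: ProteinSequence | None = None
                   ) -> pd.DataFrame:
    """Read a deep-mutational-scanning CSV with ``mutant`` and ``score``
    columns (colon- or dash-joined substitution tokens).

    When a reference is given, mutants are validated against it; unparseable
    tokens are reported with their line numbers.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "mutant" not in cols or "score" not in cols:
        raise ValueError(f"{path}: need 'mutant' and 'score' columns")
    names = []
    errors = []
    for line_no, raw in enumerate(df[cols["mutant"]].astype(str), start=2):
        name = "WT" if raw.strip() in ("WT", "wt", "") else raw.replace(":", "-")
        if reference is not None:
            try:
                parse_variant(name, reference)
            except VariantError as exc:
                errors.append(f"line {line_no}: {exc}")
        names.append(name)
    if errors:
        raise VariantError(f"{path}: unparseable mutants:\n" + "\n".join(errors))
    return pd.DataFrame({"variant": names,
                         "score": df[cols["score"]].astype(float)})


def write_metric_report(distributions: dict[str, MetricDistribution],
                        path: str | Path) -> None:
    """Per-repetition metric values as TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        names = list(distributions)
        writer.writerow(["repetition"] + names)
        n = len(next(iter(distributions.values())).values)
        for rep in range(n):
            writer.writerow([rep] + [f"{distributions[m].values[rep]:.6g}"
                                     for m in names])
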