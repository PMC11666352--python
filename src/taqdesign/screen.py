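"""In-silico screening: stream predictions over a variant scan and select
candidates by explicit multi-criteria thresholds.

The default criteria transcribe the campaign's candidate filter: catalytic
constants with dT- and dU-containing nucleotide mixes at least 20, PCR
efficiency at least 1.85, the dT/dU rate at most 1.5, error rate at most
1/3,000 (expressed as fidelity >= 3,000 nt/error), relative rate constant at
least 0.2 of the wild type, and blocking-loss scores for the antibody and
aptamer hot start at most 0.1. Thresholds are closed (equality passes).

Each rule is evaluated either on the original-scale predictive mean
("mean" mode) or as a posterior probability that the constraint holds
("chance" mode), using the Gaussian posterior on the modeling scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import __version__
from .dataset import (PropertySchema, TransformParams, default_schemas,
                      load_property_table, preprocess_targets)
from .embedding import EmbedderSpec, embed_batch
from .regression import (GPModel, GPSpec, PredictiveDistribution, RidgeModel,
                         RidgeSpec, fit_gp, fit_ridge, predict)
from .variants import (ProteinSequence, ScanSpec, Variant, apply_variant,
                       count_scan, enumerate_scan, parse_variant, read_fasta,
                       write_fasta)


@dataclass(frozen=True)
class Rule:
    """One selection rule: compare a property's prediction to a threshold.

    ``mode`` is "mean" (original-scale predictive mean vs threshold) or
    "chance" (P(constraint) >= p_level under the posterior).
    """

    threshold: float
    direction: str  # ">=" or "<="
    mode: str = "mean"
    p_level: float = 0.8

    def __post_init__(self) -> None:
        if self.direction not in (">=", "<="):
            raise ValueError("direction must be '>=' or '<='")
        if self.mode not in ("mean", "chance"):
            raise ValueError("mode must be 'mean' or 'chance'")
        if not (0.0 < self.p_level < 1.0):
            raise ValueError("p_level must lie in (0, 1)")


SelectionCriteria = dict[str, Rule]


def default_criteria(mode: str = "mean", p_level: float = 0.8) -> SelectionCriteria:
    """The campaign's published candidate filter (closed thresholds)."""
    return {
        "kcat_dT": Rule(20.0, ">=", mode, p_level),
        "kcat_dU": Rule(20.0, ">=", mode, p_level),
        "pcr_efficiency": Rule(1.85, ">=", mode, p_level),
        "dTdU_rate": Rule(1.5, "<=", mode, p_level),
        "fidelity": Rule(3000.0, ">=", mode, p_level),  # error rate <= 1/3000
        "k_rel": Rule(0.2, ">=", mode, p_level),
        "antibody_block_score": Rule(0.1, "<=", mode, p_level),
        "aptamer_block_score": Rule(0.1, "<=", mode, p_level),
    }


@dataclass
class CandidateReport:
    variant: str
    predictions: dict[str, PredictiveDistribution]
    rule_pass: dict[str, bool]
    margins: dict[str, float]
    passes: bool


@dataclass
class PropertyModel:
    """A fitted model plus the transform binding it to its property scale."""

    model: "GPModel | RidgeModel"
    params: TransformParams


def predict_scan(models: dict[str, PropertyModel],
                 variants: Iterable[Variant],
                 reference: ProteinSequence,
                 embedder: EmbedderSpec,
                 batch_size: int = 256,
                 level: float = 0.9
                 ) -> Iterator[tuple[Variant, dict[str, PredictiveDistribution]]]:
    """Stream per-variant predictions for every modeled property.

    Memory is bounded by ``batch_size``; combined with the deterministic scan
    order and an integer cursor this makes screens resumable.
    """
    batch: list[Variant] = []

    def flush():
        seqs = [apply_variant(reference, v) for v in batch]
        X = np.vstack([e.values for e in embed_batch(seqs, embedder)])
        per_prop = {prop: predict(pm.model, X, pm.params, level)
                    for prop, pm in models.items()}
        for i, v in enumerate(batch):
            yield v, {prop: per_prop[prop][i] for prop in models}

    for v in variants:
        batch.append(v)
        if len(batch) >= batch_size:
            yield from flush()
            batch = []
    if batch:
        yield from flush()


def _rule_outcome(rule: Rule, dist: PredictiveDistribution,
                  params: TransformParams) -> tuple[bool, float]:
    if rule.mode == "mean":
        margin = dist.mean - rule.threshold
        ok = dist.mean >= rule.threshold if rule.direction == ">=" \
            else dist.mean <= rule.threshold
        return ok, margin if rule.direction == ">=" else -margin
    # chance mode: probability on the modeling scale (monotone transform)
    t = float(params.forward(rule.threshold))
    if dist.sigma == 0:
        prob = float(dist.mu >= t) if rule.direction == ">=" else float(dist.mu <= t)
    else:
        z = (t - dist.mu) / dist.sigma
        prob = float(norm.sf(z)) if rule.direction == ">=" else float(norm.cdf(z))
    return prob >= rule.p_level, prob - rule.p_level


def apply_criteria(predictions: Iterable[tuple[Variant, dict[str, PredictiveDistribution]]],
                   criteria: SelectionCriteria,
                   params: dict[str, TransformParams]
                   ) -> Iterator[CandidateReport]:
    """Evaluate every rule per variant; the verdict is their conjunction."""
    for v, dists in predictions:
        missing = [p for p in criteria if p not in dists]
        if missing:
            raise KeyError(f"criteria reference unmodeled properties: {missing}")
        rule_pass, margins = {}, {}
        for prop, rule in criteria.items():
            ok, margin = _rule_outcome(rule, dists[prop], params[prop])
            rule_pass[prop] = ok
            margins[prop] = margin
        yield CandidateReport(variant=v.name, predictions=dists,
                              rule_pass=rule_pass, margins=margins,
                              passes=all(rule_pass.values()))


def passes_true_values(values: pd.DataFrame, criteria: SelectionCriteria
                       ) -> np.ndarray:
    """Which rows of a (noise-free) property table satisfy the criteria.

    Rules on properties absent from the table are skipped; used to define
    ground-truth pass sets on synthetic landscapes.
    """
    ok = np.ones(len(values), dtype=bool)
    for prop, rule in criteria.items():
        if prop not in values.columns:
            continue
        col = values[prop].to_numpy(dtype=float)
        ok &= (col >= rule.threshold) if rule.direction == ">=" \
            else (col <= rule.threshold)
    return ok


def rank_candidates(reports: Iterable[CandidateReport], objective: str,
                    direction: str = "lower", uncertainty_penalty: float = 0.0,
                    top_n: int | None = None) -> list[CandidateReport]:
    """Rank passing candidates by predictive mean with an optional
    uncertainty penalty; deterministic with a name tie-break.

    For lower-is-better objectives the score is mean + lambda * sd (smaller is
    better); for higher-is-better, mean - lambda * sd (larger is better).
    """
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")

    def score(r: CandidateReport) -> float:
        d = r.predictions[objective]
        sd = d.sigma
        return d.mean + uncertainty_penalty * sd if direction == "lower" \
            else -(d.mean - uncertainty_penalty * sd)

    ranked = sorted(reports, key=lambda r: (score(r), r.variant))
    return ranked[:top_n] if top_n is not None else ranked


# --------------------------------------------------------------------------
# End-to-end design round
# --------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.6g}"


def fit_property_models(table, schemas: Sequence[PropertySchema],
                        reference: ProteinSequence, embedder: EmbedderSpec,
                        model_kind: str = "gp", gp_spec: GPSpec | None = None,
                        ridge_spec: RidgeSpec | None = None,
                        ) -> dict[str, PropertyModel]:
    """Fit one model per training-role property of a measured table."""
    table = table.with_blocking_scores()
    usable = []
    for schema in schemas:
        if schema.name not in table.values.columns:
            continue
        exact = table.exact_values(schema.name).to_numpy(dtype=float)
        if len(exact) < 3 or np.allclose(exact, exact[0]):
            continue  # unmeasured or uninformative column: skip, don't abort
        usable.append(schema)
    schemas = usable
    targets, params = preprocess_targets(table, schemas)
    names = list(table.values.index)
    seqs = [apply_variant(reference, parse_variant(n, reference)) for n in names]
    X_all = np.vstack([e.values for e in embed_batch(seqs, embedder)])
    models: dict[str, PropertyModel] = {}
    for schema in schemas:
        if schema.training_role != "train" or schema.name not in targets.columns:
            continue
        z = targets[schema.name].to_numpy(dtype=float)
        keep = np.isfinite(z)
        if keep.sum() < 3 or np.allclose(z[keep], z[keep][0]):
            continue
        if model_kind == "gp":
            model = fit_gp(X_all[keep], z[keep], gp_spec or GPSpec())
        else:
            model = fit_ridge(X_all[keep], z[keep], ridge_spec or RidgeSpec(),
                              params[schema.name])
        models[schema.name] = PropertyModel(model, params[schema.name])
    return models


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_design_round(config: dict | str | Path) -> dict:
    """Execute one full design round from a config mapping or YAML path.

    Stages: load reference and property tables -> embed -> fit per-property
    models -> enumerate the scan -> predict -> select -> rank. Writes
    ``predictions.tsv``, ``candidates.tsv``, ``selected.fasta`` and
    ``manifest.json`` into the output directory; identical config and seed
    give byte-identical TSVs.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    stage = "configure"
    try:
        out_dir = Path(config["output_dir"])
        out_dir.mkdir(parents=True, exist_ok=True)
        seed = int(config.get("seed", 0))

        stage = "load"
        reference = read_fasta(config["reference_fasta"],
                               int(config.get("numbering_offset", 1)))
        tables = config["property_tables"]
        table = load_property_table(tables[0])
        for extra in tables[1:]:
            table = table.concat(load_property_table(extra))

        schemas = default_schemas()
        if "schemas" in config:
            overrides = {s["name"]: s for s in config["schemas"]}
            schemas = [dataclasses.replace(s, **overrides.get(s.name, {}))
                       for s in schemas]

        stage = "fit"
        emb = config.get("embedder", {})
        embedder = EmbedderSpec(dim=int(emb.get("dim", 64)),
                                seed=int(emb.get("seed", seed)),
                                bucket_size=int(emb.get("bucket_size", 16)))
        mcfg = config.get("model", {})
        gp_spec = GPSpec(kernel=mcfg.get("kernel", "matern"),
                         nu=float(mcfg.get("nu", 2.5)),
                         num_deltas=int(mcfg.get("num_deltas", 16)),
                         noise=float(mcfg.get("noise", 1e-2)),
                         max_iter=int(mcfg.get("max_iter", 50)),
                         seed=seed)
        models = fit_property_models(table, schemas, reference, embedder,
                                     model_kind=mcfg.get("kind", "gp"),
                                     gp_spec=gp_spec)

        stage = "enumerate"
        scan_cfg = config.get("scan", {})
        spec = ScanSpec(frozenset(int(p) for p in scan_cfg.get("sites", [])),
                        int(scan_cfg.get("max_substitutions", 3)))
        limit = scan_cfg.get("limit")
        variants: Iterable[Variant] = enumerate_scan(reference, spec)
        if limit is not None:
            import itertools
            variants = itertools.islice(variants, int(limit))

        stage = "predict"
        criteria = default_criteria(mode=config.get("criteria_mode", "mean"))
        criteria = {p: r for p, r in criteria.items() if p in models}
        props = list(models)
        pred_path = out_dir / "predictions.tsv"
        cand_path = out_dir / "candidates.tsv"
        params = {p: models[p].params for p in models}
        reports: list[CandidateReport] = []
        with open(pred_path, "w") as fh:
            header = ["variant"]
            for p in props:
                header += [f"{p}_mean", f"{p}_sd_model"]
            fh.write("\t".join(header) + "\n")
            stream = predict_scan(models, variants, reference, embedder,
                                  batch_size=int(config.get("batch_size", 256)))
            for report in apply_criteria(stream, criteria, params):
                row = [report.variant]
                for p in props:
                    d = report.predictions[p]
                    row += [_fmt(d.mean), _fmt(d.sigma)]
                fh.write("\t".join(row) + "\n")
                if report.passes:
                    reports.append(report)

        stage = "select"
        objective = config.get("objective", "rt90")
        obj_dir = config.get("objective_direction", "lower")
        top_n = int(config.get("top_n", 16))
        lam = float(config.get("uncertainty_penalty", 0.0))
        ranked = rank_candidates(reports, objective, obj_dir, lam, top_n) \
            if objective in props else reports[:top_n]
        with open(cand_path, "w") as fh:
            header = ["rank", "variant", "passes"]
            for p in props:
                header += [f"{p}_mean", f"{p}_margin"]
            fh.write("\t".join(header) + "\n")
            for rank, r in enumerate(ranked, start=1):
                row = [str(rank), r.variant, "yes"]
                for p in props:
                    row += [_fmt(r.predictions[p].mean),
                            _fmt(r.margins.get(p, float("nan")))]
                fh.write("\t".join(row) + "\n")

        stage = "export"
        fasta_path = out_dir / "selected.fasta"
        selected = [apply_variant(reference, parse_variant(r.variant, reference))
                    for r in ranked]
        write_fasta(selected, fasta_path)

        manifest = {
            "version": __version__,
            "seed": seed,
            "embedder_digest": embedder.digest(),
            "reference_digest": reference.digest(),
            "scan_counts": count_scan(reference, spec),
            "n_passing": len(reports),
            "n_selected": len(ranked),
            "digests": {p.name: _sha256(p)
                        for p in (pred_path, cand_path, fasta_path)},
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"design round failed at stage {stage!r}: {exc}") from exc
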