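"""Synthetic variant -> multi-property landscapes and sequencing counts.

The generator emulates the structure the design loop assumes rather than the
biophysics: a single latent "binding/activity" factor b(v), additive over
per-site substitution effects with sparse pairwise epistasis, drives every
measured property through a sign-constrained loading. The signs reproduce the
correlation pattern observed across the real mutant panel: reverse-
transcriptase dCq co-varies positively with K_d, fidelity, the dT/dU rate and
the LNA delay (all of them fall as the latent activity rises), and negatively
with the catalytic constants and the relative rate constant. An optional
second latent factor decouples fidelity to emulate exception mutants.

Measured tables add per-property Gaussian noise on the transform scale, apply
the same censoring rules as the real tables (long-template dCq falls below
the detection limit for weak enzymes; LNA delays are only quantifiable up to
an upper bound), and draw hot-start blocking levels from a latent-dependent
ordinal model. Amplicon sequencing counts are simulated from the binomial
inverse of the fidelity estimator: expected pool substitution frequency
f = p * n / E at the configured coverage.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .dataset import PropertyTable
from .variants import (AA_ALPHABET, Mutation, ProteinSequence, Variant)


@dataclass(frozen=True)
class PropertyConfig:
    """How one property derives from the latent factor.

    On the transform scale (log for log-normal properties) the true value is
    ``intercept + loading * b``; measurement noise (sd ``noise_sd``) is added
    on the same scale before back-transforming.
    """

    transform: str  # "log" | "identity"
    intercept: float
    loading: float
    noise_sd: float
    censor_above: float | None = None   # report ">bound" beyond this value
    detection_limit: float | None = None  # report N/A beyond this value
    fidelity_factor: float = 0.0        # loading on the optional second factor


def default_properties() -> dict[str, PropertyConfig]:
    """Defaults chosen so property ranges match the real mutant panel.

    Intercepts anchor at the wild-type values of the measured tables (b = 0
    is the WT), so dCq spans roughly -2..18, K_d roughly 0.5..200 nM,
    fidelity thousands of nt/error, catalytic constants tens of 1/s — and,
    as in the real panel, the WT itself satisfies the continuous selection
    thresholds."""
    return {
        "rt90": PropertyConfig("identity", 4.4, -6.0, 1.0, detection_limit=18.0),
        "rt116": PropertyConfig("identity", 5.3, -6.0, 1.0, detection_limit=18.0),
        "rt201": PropertyConfig("identity", 15.3, -6.0, 1.2, detection_limit=18.0),
        "rt526": PropertyConfig("identity", 14.3, -5.0, 1.2, detection_limit=14.5),
        "k_rel": PropertyConfig("log", 0.0, 0.8, 0.3),
        "fidelity": PropertyConfig("log", math.log(6000.0), -0.45, 0.25,
                                   fidelity_factor=0.35),
        "dTdU_rate": PropertyConfig("log", math.log(1.29), -0.3, 0.12),
        "pcr_efficiency": PropertyConfig("identity", 1.90, 0.03, 0.02),
        "kcat_dT": PropertyConfig("log", math.log(35.0), 0.55, 0.2),
        "kcat_dU": PropertyConfig("log", math.log(33.0), 0.65, 0.2),
        "kd": PropertyConfig("log", math.log(6.2), -1.0, 0.3),
        "lna3_delay": PropertyConfig("log", math.log(10.7), -0.6, 0.3,
                                     censor_above=40.0),
    }


@dataclass(frozen=True)
class LandscapeConfig:
    """Synthetic landscape at desk scale.

    A random reference of length ``reference_length`` carries
    ``n_combinatorial_sites`` sites; each site allows ``residues_per_site``
    alternative residues. Substitution effects are ``site effect + residue
    deviation`` draws; sampled site pairs interact with probability
    ``epistasis_probability``.
    """

    reference_length: int = 120
    n_combinatorial_sites: int = 8
    residues_per_site: int = 6
    site_effect_mean: float = 0.0
    site_effect_sd: float = 0.55
    residue_effect_sd: float = 0.25
    epistasis_probability: float = 0.15
    epistasis_sd: float = 0.2
    fidelity_factor_sd: float = 0.0   # > 0 switches on the second latent factor
    blocking_slope: float = 0.3
    blocking_noise_sd: float = 0.3
    seed: int = 0
    properties: tuple[tuple[str, PropertyConfig], ...] = field(
        default_factory=lambda: tuple(default_properties().items()))


@dataclass(frozen=True)
class SeqSimConfig:
    """Amplicon sequencing simulation for the fidelity estimator."""

    true_p: float = 3e-5
    efficiency: float = 2.0
    cycles: int = 30
    coverage: int = 100_000
    amplicon_length: int = 99
    primer_intervals: tuple[tuple[int, int], ...] = ((0, 20), (79, 99))
    transition_weight: float = 2.0
    transversion_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_p <= 1e-2):
            raise ValueError("true_p must lie in [0, 1e-2]")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")


@dataclass
class Landscape:
    reference: ProteinSequence
    variants: list[Variant]
    latent: pd.Series                 # b(v) per variant name
    true_values: pd.DataFrame         # noise-free natural-scale properties
    measured: PropertyTable           # noisy, censored table


def _draw_effects(cfg: LandscapeConfig, rng: np.random.Generator,
                  reference: ProteinSequence):
    sites = sorted(rng.choice(np.arange(2, cfg.reference_length),
                              size=cfg.n_combinatorial_sites, replace=False))
    effects: dict[tuple[int, str], float] = {}
    alphabet: dict[int, list[str]] = {}
    for site in sites:
        wt = reference.residue_at(int(site))
        choices = [aa for aa in AA_ALPHABET if aa != wt]
        picked = list(rng.choice(choices, size=cfg.residues_per_site, replace=False))
        alphabet[int(site)] = sorted(picked)
        base = rng.normal(cfg.site_effect_mean, cfg.site_effect_sd)
        for aa in alphabet[int(site)]:
            effects[(int(site), aa)] = base + rng.normal(0, cfg.residue_effect_sd)
    pair_terms: dict[tuple[int, int], float] = {}
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            if rng.random() < cfg.epistasis_probability:
                pair_terms[(int(a), int(b))] = rng.normal(0, cfg.epistasis_sd)
    return [int(s) for s in sites], alphabet, effects, pair_terms


def _sample_variants(cfg: LandscapeConfig, rng: np.random.Generator,
                     reference: ProteinSequence, sites, alphabet,
                     n_variants: int) -> list[Variant]:
    space = sum(math.comb(len(sites), k) * cfg.residues_per_site ** k
                for k in (1, 2, 3))
    if n_variants > space:
        raise ValueError(f"{n_variants} variants exceed the enumerable space ({space})")
    seen = set()
    out: list[Variant] = []
    while len(out) < n_variants:
        k = rng.choice([1, 2, 3], p=[0.3, 0.4, 0.3])
        combo = sorted(rng.choice(sites, size=k, replace=False))
        muts = tuple(Mutation(int(p), reference.residue_at(int(p)),
                              str(rng.choice(alphabet[int(p)])))
                     for p in combo)
        v = Variant(muts)
        if v.name not in seen:
            seen.add(v.name)
            out.append(v)
    return out


def generate_landscape(config: LandscapeConfig, n_variants: int = 200) -> Landscape:
    """Draw a reference, a variant sample (plus WT), and its property tables."""
    rng = np.random.default_rng(config.seed)
    residues = "".join(rng.choice(list(AA_ALPHABET), size=config.reference_length))
    reference = ProteinSequence("synthetic-ref", residues)
    sites, alphabet, effects, pair_terms = _draw_effects(config, rng, reference)
    variants = [Variant(())] + _sample_variants(config, rng, reference, sites,
                                                alphabet, n_variants)

    def latent_of(v: Variant) -> float:
        b = sum(effects[(m.position, m.mut_aa)] for m in v.mutations)
        pos = [m.position for m in v.mutations]
        for i, a in enumerate(pos):
            for c in pos[i + 1:]:
                b += pair_terms.get((a, c), 0.0)
        return b

    names = [v.name for v in variants]
    latent = pd.Series([latent_of(v) for v in variants], index=names)
    f2 = pd.Series(rng.normal(0, config.fidelity_factor_sd, len(variants))
                   if config.fidelity_factor_sd > 0 else np.zeros(len(variants)),
                   index=names)

    props = dict(config.properties)
    true_values = pd.DataFrame(index=names, columns=list(props), dtype=float)
    meas_values = pd.DataFrame(index=names, columns=list(props), dtype=float)
    censor = pd.DataFrame("exact", index=names, columns=list(props))
    for prop, pc in props.items():
        clean = pc.intercept + pc.loading * latent.to_numpy() \
            + pc.fidelity_factor * f2.to_numpy()
        noisy = clean + rng.normal(0, pc.noise_sd, len(variants))
        if pc.transform == "log":
            true_values[prop] = np.exp(clean)
            natural = np.exp(noisy)
        else:
            true_values[prop] = clean
            natural = noisy
        meas_values[prop] = natural
        if pc.censor_above is not None:
            over = natural > pc.censor_above
            meas_values.loc[over, prop] = pc.censor_above
            censor.loc[over, prop] = "above"
        if pc.detection_limit is not None:
            out_of_range = natural > pc.detection_limit
            meas_values.loc[out_of_range, prop] = np.nan
            censor.loc[out_of_range, prop] = "below_detection"

    # blocking: loss of the hot-start block becomes likelier as b rises
    levels = []
    for which in ("antibody", "aptamer"):
        z = config.blocking_slope * latent.to_numpy() \
            + rng.normal(0, config.blocking_noise_sd, len(variants))
        lv = np.where(z < 0.8, "Strong", np.where(z < 1.2, "Weak", "Absent"))
        levels.append(pd.Series(lv, index=names, name=f"{which}_blocking"))
    blocking = pd.concat(levels, axis=1)
    rounds = pd.Series("I", index=names)
    measured = PropertyTable(meas_values, censor, blocking, rounds)
    return Landscape(reference=reference, variants=variants, latent=latent,
                     true_values=true_values, measured=measured)


def simulate_counts(config: SeqSimConfig) -> list:
    """Per-position base counts under the inverse of p = E f / n.

    Alt calls at each unmasked position are binomial with success probability
    f = p n / E, split across the three non-reference bases by transition/
    transversion weights. Primer positions are emitted flagged.
    """
    from .fidelity import BASES, TRANSITIONS, PositionCounts

    f_true = config.true_p * config.cycles / config.efficiency
    if f_true > 1:
        raise ValueError("inconsistent config: p*n/E exceeds 1")
    rng = np.random.default_rng(config.seed)
    refs = rng.choice(list(BASES), size=config.amplicon_length)
    out = []
    for pos in range(config.amplicon_length):
        ref = str(refs[pos])
        in_primer = any(a <= pos < b for a, b in config.primer_intervals)
        alts = [b for b in BASES if b != ref]
        weights = np.array([config.transition_weight if (ref, b) in TRANSITIONS
                            else config.transversion_weight for b in alts])
        weights = weights / weights.sum()
        n_alt = rng.binomial(config.coverage, f_true)
        split = rng.multinomial(n_alt, weights)
        counts = {b: int(c) for b, c in zip(alts, split)}
        counts[ref] = config.coverage - n_alt
        out.append(PositionCounts(pos, ref, counts, in_primer=in_primer))
    return out


def recovery_experiment(config: LandscapeConfig | None = None,
                        n_variants: int = 200, train_size: int = 33,
                        n_seeds: int = 20, primary: str = "rt90",
                        shuffle_control: bool = True) -> dict:
    """Desk-scale replica of one design-loop round, repeated over seeds.

    Per seed: generate a landscape, train a GP for the primary property on a
    33-point sample (the scale of the campaign's second-round dataset), score
    Spearman on the held-out truth, and run the threshold screen on held-out
    variants to measure how strongly selection enriches truly-passing
    variants over random picking.
    """
    from .embedding import EmbedderSpec, embedding_matrix
    from .regression import GPSpec, fit_gp
    from .model_selection import spearman_rank
    from .screen import default_criteria, passes_true_values

    base = config or LandscapeConfig()
    criteria = default_criteria()
    spearmans, shuffled, enrichments = [], [], []
    for s in range(n_seeds):
        cfg = LandscapeConfig(**{**base.__dict__, "seed": base.seed + s})
        land = generate_landscape(cfg, n_variants)
        espec = EmbedderSpec(dim=64, seed=cfg.seed)
        from .variants import apply_variant
        seqs = [apply_variant(land.reference, v) for v in land.variants]
        X = embedding_matrix(seqs, espec)
        y = land.measured.values[primary].to_numpy(dtype=float)
        exact = land.measured.censor[primary].to_numpy() == "exact"
        idx = np.flatnonzero(exact)
        rng = np.random.default_rng(cfg.seed)
        train = rng.choice(idx, size=train_size, replace=False)
        test = np.setdiff1d(idx, train)
        model = fit_gp(X[train], y[train], GPSpec(seed=cfg.seed))
        pred, _ = model.predict_mean_var(X[test])
        truth = land.true_values[primary].to_numpy(dtype=float)[test]
        spearmans.append(spearman_rank(pred, truth))
        if shuffle_control:
            y_shuf = y[train].copy()
            rng.shuffle(y_shuf)
            m2 = fit_gp(X[train], y_shuf, GPSpec(seed=cfg.seed))
            p2, _ = m2.predict_mean_var(X[test])
            shuffled.append(spearman_rank(p2, truth))

        # screen enrichment: model every criterion property on its transform
        # scale (as the design-round pipeline does), select held-out variants
        # by the thresholds on the back-transformed predictive mean, and
        # compare the truly-passing fraction inside vs overall
        from .dataset import TransformParams, default_schemas
        from .regression import predict as predict_dist
        tmap = {s.name: s.transform for s in default_schemas()}
        held = np.setdiff1d(np.arange(len(land.variants)), train)
        truly_pass = passes_true_values(land.true_values.iloc[held], criteria)
        base_rate = float(np.mean(truly_pass))
        pred_pass = np.ones(len(held), dtype=bool)
        for prop, rule in criteria.items():
            if prop not in land.measured.values.columns:
                continue
            col = land.measured.values[prop].to_numpy(dtype=float)
            ok = (land.measured.censor[prop].to_numpy() == "exact") \
                & np.isin(np.arange(len(col)), train)
            fit_idx = np.flatnonzero(ok)
            if len(fit_idx) < 5 or np.allclose(col[fit_idx], col[fit_idx][0]):
                continue
            y_raw = col[fit_idx]
            transform = tmap.get(prop, "identity")
            y_t = np.log(y_raw) if transform == "log" else y_raw
            mean, sd = float(np.mean(y_t)), float(np.std(y_t))
            if sd == 0:
                continue
            params = TransformParams(transform, mean, sd)
            mdl = fit_gp(X[fit_idx], (y_t - mean) / sd, GPSpec(seed=cfg.seed))
            means = np.array([d.mean for d in predict_dist(mdl, X[held], params)])
            pred_pass &= (means >= rule.threshold) if rule.direction == ">=" \
                else (means <= rule.threshold)
        if pred_pass.any() and base_rate > 0:
            precision = float(np.mean(truly_pass[pred_pass]))
            enrichments.append(precision / base_rate)
        else:
            enrichments.append(float("nan"))
    return {
        "median_spearman": float(np.nanmedian(spearmans)),
        "spearman_values": spearmans,
        "median_shuffled_spearman": (float(np.nanmedian(shuffled))
                                     if shuffled else float("nan")),
        "median_enrichment": float(np.nanmedian(enrichments)),
        "enrichment_values": enrichments,
    }
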