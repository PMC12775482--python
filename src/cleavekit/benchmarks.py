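"""End-to-end simulator benchmarks.

Self-contained experiments that exercise the whole pipeline on the synthetic
protease panel: predictor recovery (accuracy, noise-floor comparison,
uncertainty calibration), conditional-steering of the generator toward a
selective cleavage profile, and nomination-versus-baseline comparisons. The
acceptance machinery and the test suite both run these; every experiment is
deterministic given its seed.

Problem sizes default to desk-scale runs that converge on a single CPU in a
few minutes; docs/methods.md records the choices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .design import DesignObjective, nominate, site_independent_sample
from .generator import (
    GeneratorConfig, conditional_seed_profiles, filter_generations, sample,
    train_generator, heldout_losses_by_pathway,
)
from .predictor import (
    PredictorConfig, evaluate, predict, predictions_to_arrays,
    train_predictor_ensemble,
)
from .scoring import selectivity_score
from .synthetic_data import build_panel, raw_score_matrix, simulate_library

logger = logging.getLogger("cleavekit")


def _heldout_scores(panel, truth, n, seed):
    """Independently simulated peptides scored on the training library's
    standardization scale: returns (sequences, Z_noisy, Z_true)."""
    rng = np.random.default_rng(seed)
    ev, evt = simulate_library(panel, n, 0.3, seed=seed, return_truth=True)
    Z_true = (evt.raw - truth.col_mean) / truth.col_sd
    Z = Z_true + rng.normal(0, panel.noise_sd, evt.raw.shape) / truth.col_sd
    return ev.sequences, Z, Z_true


def predictor_recovery(
    seed: int = 0,
    M: int = 4,
    n: int = 4000,
    noise_sd: float = 0.5,
    K: int = 5,
    epochs: int = 40,
    n_eval: int = 8000,
) -> dict:
    """Train a K-member transformer ensemble on a simulated screen and
    measure held-out recovery: per-protease Pearson r, aggregate MAE against
    the irreducible-noise floor, and the pooled Spearman correlation between
    ensemble uncertainty and the error against the noiseless truth."""
    panel = build_panel(M, 10, max(1, M // 2), seed=seed, noise_sd=noise_sd)
    lib, truth = simulate_library(panel, n, 0.3, seed=seed + 1, return_truth=True)
    config = PredictorConfig(epochs=epochs, warmup_steps=500, seed=seed)
    ensemble = train_predictor_ensemble(lib, config, K=K)

    seqs, Z, Z_true = _heldout_scores(panel, truth, n_eval, seed + 2)
    zhat, sigma = predictions_to_arrays(predict(ensemble, seqs))
    metrics = evaluate(zhat, Z, lib.panel, thresholds=())
    r = metrics["pearson_r"]
    mae = float(np.abs(zhat - Z).mean())
    mae_floor = float(np.abs(Z - Z_true).mean())
    rho = float(spearmanr(sigma.ravel(), np.abs(zhat - Z_true).ravel())[0])
    out = {
        "pearson_r": r,
        "pearson_r_min": float(min(r.values())),
        "mae": mae,
        "mae_noise_floor": mae_floor,
        "mae_over_floor": mae / mae_floor,
        "sigma_error_spearman": rho,
        "ensemble": ensemble,
        "panel": panel,
        "library": lib,
        "truth": truth,
    }
    logger.info(
        "predictor recovery: r_min=%.3f mae=%.3f floor=%.3f rho=%.4f",
        out["pearson_r_min"], mae, mae_floor, rho,
    )
    return out


@dataclass
class SteeringContext:
    """Trained generator plus the simulated world it was trained on."""

    panel: object
    library: object
    truth: object
    model: object


def train_steering_context(
    seed: int = 0,
    M: int = 6,
    n: int = 3000,
    epochs: int = 20,
) -> SteeringContext:
    """Simulate a panel with a private-motif protease and train the
    conditional generator on its screen."""
    panel = build_panel(M, 10, max(1, M // 2), seed=seed + 10, noise_sd=0.5)
    lib, truth = simulate_library(panel, n, 0.3, seed=seed + 11, return_truth=True)
    config = GeneratorConfig(epochs=epochs, warmup_steps=300, seed=seed)
    model = train_generator(lib, config)
    return SteeringContext(panel=panel, library=lib, truth=truth, model=model)


def _true_z(ctx: SteeringContext, sequences) -> np.ndarray:
    raw = raw_score_matrix(ctx.panel, list(sequences))
    return (raw - ctx.truth.col_mean) / ctx.truth.col_sd


def conditional_steering(ctx: SteeringContext, seed: int = 0, n_gen: int = 800) -> dict:
    """Median true selectivity for the private-motif protease: conditional
    generations seeded with the library's top-50 selective profiles versus
    unconditional generations."""
    target = ctx.panel.private_protease
    tags = conditional_seed_profiles(ctx.library.Z, ctx.library.panel,
                                     target, "selectivity", k=50)
    tagmat = np.tile(tags, (int(np.ceil(n_gen / len(tags))), 1))[:n_gen]

    uncond = sample(ctx.model, n_gen, temperature=1.0, repeat_penalty=1.2,
                    seed=seed + 21)
    cond = sample(ctx.model, n_gen, temperature=1.2, repeat_penalty=1.2,
                  tag=tagmat, seed=seed + 22)
    u10, u_report = filter_generations(uncond, ctx.panel.L, ctx.library)
    c10, c_report = filter_generations(cond, ctx.panel.L, ctx.library)

    sel_u = selectivity_score(_true_z(ctx, u10), target)
    sel_c = selectivity_score(_true_z(ctx, c10), target)
    out = {
        "median_selectivity_unconditional": float(np.median(sel_u)),
        "median_selectivity_conditional": float(np.median(sel_c)),
        "unconditional_kept_fraction": u_report["n_out"] / u_report["n_in"],
        "conditional_kept_fraction": c_report["n_out"] / c_report["n_in"],
        "pathway_losses": heldout_losses_by_pathway(
            ctx.model, ctx.library.subset(range(min(300, len(ctx.library))))),
    }
    mu, mc = out["median_selectivity_unconditional"], out["median_selectivity_conditional"]
    out["steering_fold"] = mc / mu if mu > 1e-6 else float("inf") if mc > 0 else 0.0
    logger.info("steering: uncond median %.3f, cond median %.3f", mu, mc)
    return out


def nomination_vs_baseline(
    ctx: SteeringContext,
    seed: int = 0,
    n_reps: int = 20,
    pool_n: int = 300,
    n_nominees: int = 24,
    K: int = 3,
    epochs: int = 25,
) -> dict:
    """Repeat seeded rounds of (generate pool -> predict -> nominate) against
    equal-size site-independent baselines; count how often each nomination
    route yields a higher mean true Z for the target protease."""
    target = ctx.panel.private_protease
    target_name = ctx.library.panel[target]
    config = PredictorConfig(epochs=epochs, warmup_steps=500, seed=seed + 30)
    ensemble = train_predictor_ensemble(ctx.library, config, K=K)

    sel_true = selectivity_score(ctx.truth.Z_true, target)
    top_sel = [ctx.library.sequences[i] for i in np.argsort(-sel_true)[:50]]
    tags = conditional_seed_profiles(ctx.library.Z, ctx.library.panel,
                                     target, "selectivity", k=50)

    wins_eff, wins_sel, details = 0, 0, []
    for rep in range(n_reps):
        rs = seed + 100 + rep
        # efficiency route: unconditional pool, rank by Zhat - sigma
        pool = sample(ctx.model, pool_n, temperature=1.0, repeat_penalty=1.2,
                      seed=rs)
        pool, _ = filter_generations(pool, ctx.panel.L, ctx.library)
        zhat, sigma = predictions_to_arrays(predict(ensemble, pool))
        eff = nominate(pool, zhat, sigma, ctx.library.panel,
                       DesignObjective(target=target_name, mode="efficiency",
                                       n_nominees=n_nominees))
        base_eff = site_independent_sample(ctx.library, n_nominees, seed=rs)

        # selectivity route: conditional pool, rank by predicted selectivity
        tagmat = np.tile(tags, (int(np.ceil(pool_n / len(tags))), 1))[:pool_n]
        cpool = sample(ctx.model, pool_n, temperature=1.2, repeat_penalty=1.2,
                       tag=tagmat, seed=rs + 5000)
        cpool, _ = filter_generations(cpool, ctx.panel.L, ctx.library)
        czhat, csigma = predictions_to_arrays(predict(ensemble, cpool))
        sel = nominate(cpool, czhat, csigma, ctx.library.panel,
                       DesignObjective(target=target_name, mode="selectivity",
                                       n_nominees=n_nominees))
        base_sel = site_independent_sample(top_sel, n_nominees, seed=rs + 7000)

        z_eff = _true_z(ctx, eff["sequence"])[:, target].mean()
        z_beff = _true_z(ctx, base_eff)[:, target].mean()
        z_sel = _true_z(ctx, sel["sequence"])[:, target].mean()
        z_bsel = _true_z(ctx, base_sel)[:, target].mean()
        wins_eff += z_eff > z_beff
        wins_sel += z_sel > z_bsel
        details.append({"rep": rep, "z_eff": z_eff, "z_base_eff": z_beff,
                        "z_sel": z_sel, "z_base_sel": z_bsel})

    out = {
        "n_reps": n_reps,
        "efficiency_win_fraction": wins_eff / n_reps,
        "selectivity_win_fraction": wins_sel / n_reps,
        "details": details,
        "ensemble": ensemble,
    }
    logger.info("nomination wins: efficiency %.2f, selectivity %.2f",
                out["efficiency_win_fraction"], out["selectivity_win_fraction"])
    return out
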