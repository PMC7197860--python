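"""Top-level replicate experiments over the generating-model grid.

``run_model_grid`` reproduces the structure of the simulation study: for
each genotype-effect model it simulates replicate cohorts, turns residuals
into phenotypes, scores them with the simplified PPLD, and reports the
mean/s.d. of each PPLD distribution together with the pairwise
correlations between PPLDs computed from different residual kinds on the
same replicates.  Replicate counts default to desk scale (tens to a
hundred) and are fully configurable.
"""

from __future__ import annotations

import numpy as np

from .ppld import DEFAULT_PI, score_experiment

__all__ = ["run_model_grid"]


def run_model_grid(
    models=(1, 2),
    residual_kinds=("mr", "dr", "ote", "olrr"),
    reps: int = 100,
    n: int = 500,
    seed=None,
    pi: float = DEFAULT_PI,
    **score_kwargs,
) -> dict:
    """PPLD summary report across generating models.

    Returns a JSON-serializable dict: for each model, the per-residual-kind
    mean and s.d. of the replicate PPLD distribution, the correlation
    matrix across kinds, and (under ``"ppld"``) the raw replicate values
    for optional violin-plot style exports.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    residual_kinds = tuple(residual_kinds)
    report = {
        "config": {
            "models": list(models),
            "residual_kinds": list(residual_kinds),
            "reps": reps,
            "n": n,
            "pi": pi,
        },
        "models": {},
    }
    for model_id in models:
        result = score_experiment(
            model_id, residual_kinds, reps=reps, n=n, seed=rng, pi=pi, **score_kwargs
        )
        corr = result["correlations"]
        report["models"][str(model_id)] = {
            "mean": {k: float(result["mean"][k]) for k in residual_kinds},
            "sd": {k: float(result["sd"][k]) for k in residual_kinds},
            "correlations": {
                f"{a}&{b}": float(corr.loc[a, b])
                for i, a in enumerate(residual_kinds)
                for b in residual_kinds[i + 1 :]
            },
            "ppld": {k: [float(v) for v in result["ppld"][k]] for k in residual_kinds},
        }
    return report
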