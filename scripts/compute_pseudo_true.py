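"""Large-sample oracle for the generator's implied same-sex-preference
(MP2c.3 proximity) coefficients.

Scan sampling aggregates per-scan join probabilities nonlinearly, so the
logit-scale age/sex coefficients implied by the generator are not identical
to its probability-scale config parameters. This script measures them
directly: it pools MP2c.3 proximity response rows from many independent
replicate troops generated under the default configuration and fits a plain
binomial logistic GLM (hand-rolled IRLS — deliberately independent of the
pipeline's mixed-model backend). The resulting pseudo-true coefficients are
frozen into the parameter-recovery test.

Run from the repository root:  python scripts/compute_pseudo_true.py [n_reps]
"""

import sys

import numpy as np
import pandas as pd

from matrinet import SimulationConfig, simulate_dataset
from matrinet.models import spec_by_label, build_model_table
from matrinet.pipeline import assemble_rows, build_context


def irls_logistic(X: np.ndarray, k: np.ndarray, n: np.ndarray, max_iter: int = 100) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n * mu * (1 - mu)
        z = eta + (k - n * mu) / np.maximum(w, 1e-10)
        beta_new = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            return beta_new
        beta = beta_new
    return beta


def main(n_reps: int = 40) -> None:
    spec = spec_by_label("MP2c.3 proximity")
    frames = []
    for seed in range(n_reps):
        cfg = SimulationConfig(rng_seed=seed)
        ctx = build_context(simulate_dataset(cfg))
        rows = build_model_table(assemble_rows(spec, ctx, np.random.default_rng(0)), spec)
        frames.append(rows)
        print(f"seed {seed}: {len(rows)} rows", flush=True)
    df = pd.concat(frames, ignore_index=True)
    X = np.column_stack(
        [
            np.ones(len(df)),
            df.age,
            df.sex,
            df.age * df.sex,
            df.n_offspring,
            df.mother_rank,
            (df.troop == "T2").astype(float),
        ]
    )
    beta = irls_logistic(X, df.k.to_numpy(float), df.n.to_numpy(float))
    names = ["intercept", "age", "sex", "age:sex", "n_offspring", "mother_rank", "troopT2"]
    print(f"\npooled rows: {len(df)}")
    for nm, b in zip(names, beta):
        print(f"{nm:12s} {b:+.5f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 40)
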