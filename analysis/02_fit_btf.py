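"""Fit the Bayesian tensor factorization on the full study world.

Runs the Gibbs sampler at the world's true rank on all observed cells
(evidence + outcomes), scores every unobserved target-indication pair, and
exports the posterior-mean latent embeddings of indications for external
2-D visualization.

Reads results/world/ (run 01_simulate_world.py first); writes
results/fit/posterior_scores.tsv and results/fit/indication_embedding.tsv.
"""

import sys
from pathlib import Path

import numpy as np

from trialtensor import btf, downstream
from trialtensor.experiments import SYNTH_ALPHA, default_world
from trialtensor.util import derive_seed

OUT = Path(__file__).resolve().parent.parent / "results" / "fit"
SEED = 7


def main() -> None:
    world = default_world(derive_seed(SEED, "recovery-world"))
    observed = set(map(tuple, world.outcomes.pairs()))
    pairs = np.array(
        [
            (i, j)
            for i in range(world.config.M)
            for j in range(world.config.N)
            if (i, j) not in observed
        ]
    )
    cells = np.column_stack(
        [pairs, np.full(len(pairs), world.tensor.outcome_slice_index)]
    )
    cfg = btf.GibbsConfig(
        D=world.config.D_true,
        burn_in=200,
        n_samples=200,
        alpha=SYNTH_ALPHA,
        seed=derive_seed(SEED, "full-fit"),
        save_factors=True,
    )
    summary = btf.run_mcmc(world.tensor, world.attributes, cfg, cells)

    OUT.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    pd.DataFrame(
        {
            "target": [world.registry.targets[i] for i in pairs[:, 0]],
            "indication": [world.registry.indications[j] for j in pairs[:, 1]],
            "posterior_mean": summary.mean,
            "posterior_sd": summary.sd,
        }
    ).to_csv(OUT / "posterior_scores.tsv", sep="\t", index=False)

    emb = downstream.export_latent_embedding(
        summary, "indication", world.registry, world.indication_groups
    )
    emb.to_csv(OUT / "indication_embedding.tsv", sep="\t", index=False)

    print(
        f"scored {len(pairs)} untested pairs "
        f"(posterior mean range {summary.mean.min():.2f}..{summary.mean.max():.2f})"
    )
    print(f"embedding of {len(emb)} indications x {world.config.D_true} factors")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
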