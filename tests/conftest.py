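import numpy as np
import pytest

import thermotrace as tt


@pytest.fixture(scope="session")
def quartet_tree() -> tt.RootedTree:
    return tt.RootedTree.from_newick(
        "((a:0.12,b:0.31):0.2,(c:0.15,d:0.07):0.4);"
    )


def random_gg_params(tree: tt.RootedTree, rng: np.random.Generator,
                     n_categories: int = 8) -> tt.GGParams:
    thetas = {v: float(rng.uniform(0.15, 0.85))
              for v in range(tree.n_nodes) if v != tree.root}
    return tt.GGParams(
        theta_root=float(rng.uniform(0.2, 0.8)),
        theta_branch=thetas,
        kappa=float(rng.uniform(0.5, 5.0)),
        alpha=float(rng.uniform(0.3, 2.0)),
        n_categories=n_categories,
    )


@pytest.fixture(scope="session")
def small_study() -> tt.SyntheticStudy:
    """A fast, reduced-size synthetic study shared across tests."""
    cfg = tt.StudyConfig(n_taxa=8, n_sites=400)
    return tt.make_synthetic_study(cfg, seed=7)
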