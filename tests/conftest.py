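import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import regomax as rx

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def net500():
    """Seed-1 synthetic background used across the numeric suites."""
    return rx.generate_metacore_like(rx.SyntheticSpec(N=500, seed=1))


@pytest.fixture(scope="session")
def model500(net500):
    return rx.build_google_matrix(net500, alpha=0.85)


@pytest.fixture(scope="session")
def pagerank500(model500):
    return rx.compute_pagerank(model500).P


@pytest.fixture(scope="session")
def reduced500(model500, pagerank500):
    rng = np.random.default_rng(0)
    subset = rng.choice(500, 20, replace=False)
    return rx.compute_reduced_google(model500, subset, pagerank=pagerank500)


def make_group_frame(node_ids, counts=(4, 20, 20)):
    """44-style group frame: counts of (t, u, d) rows over the given ids."""
    rows, kg, k = [], 1, 0
    for sub, cnt in zip("tud", counts):
        for i in range(1, cnt + 1):
            rows.append(
                dict(Kg=kg, subgroup=sub, subgroup_index=i,
                     node_id=node_ids[k], protein_name=node_ids[k])
            )
            kg += 1
            k += 1
    return pd.DataFrame(rows)


def make_planted_instance(seed, n=600, n_planted=3, boost=10):
    """Background network + internal group + planted external influencers.

    The 44 internals are a random draw; the planted influencers are outside
    nodes with no pre-existing link into the top-5 up/down targets, each wired
    with ``boost`` direct links into the targets and ``boost`` extra incoming
    links.
    """
    net = rx.generate_metacore_like(rx.SyntheticSpec(N=n, seed=seed))
    rng = np.random.default_rng(seed + 1000)
    perm = rng.permutation(n)
    internal = perm[:44]
    frame = make_group_frame([net.node_ids[j] for j in internal])
    groups = rx.ProteinGroupTable(frame)
    targets = frame[(frame.subgroup.isin(["u", "d"])) & (frame.subgroup_index <= 5)][
        "node_id"
    ].tolist()
    tgt_idx = {net.node_index(t) for t in targets}
    linked = {int(s) for s, t in zip(net.src, net.tgt) if int(t) in tgt_idx}
    outside = [int(j) for j in perm[44:] if int(j) not in linked]
    planted = [net.node_ids[j] for j in outside[:n_planted]]
    truth = rx.PlantedTruth(
        internal_ids=frame["node_id"].tolist(),
        target_ids=targets,
        planted_influencer_ids=planted,
        boost=boost,
    )
    aug = rx.plant_external_influencers(net, truth, seed=seed + 2000)
    groups.bind(aug)
    return net, aug, groups, truth


@pytest.fixture(scope="session")
def planted_instance():
    return make_planted_instance(seed=7)


def random_stochastic(nr, rng):
    """Random strictly-positive column-stochastic matrix."""
    m = rng.uniform(0.05, 1.0, size=(nr, nr))
    return m / m.sum(axis=0)


def reduced_from_matrix(GR, alpha=0.85):
    """Wrap a bare column-stochastic matrix as a ReducedSet for sensitivity."""
    pr = rx.reduced_pagerank(GR, tol=1e-15)
    nr = GR.shape[0]
    return rx.ReducedSet(
        subset=np.arange(nr), GR=GR, Grr=np.zeros((nr, nr)),
        Gpr=GR.copy(), Gqr=np.zeros((nr, nr)),
        lambda_c=0.5, Pr=pr, method="dense_solve", alpha=alpha,
    )
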