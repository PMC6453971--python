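import itertools

import numpy as np
import pytest

import smacotype as st
from smacotype.simulate import SimulationConfig, build_scaffold, evolve_lineages


def random_circle(rng, L, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=L))


@pytest.fixture(scope="session")
def scaffolds():
    """A dozen rejection-checked scaffolds (mixed organizations) with truth."""
    out = []
    for seed in range(12):
        rng = np.random.default_rng(seed)
        cfg = SimulationConfig(organization="IV" if seed % 2 else "V")
        out.append(build_scaffold(cfg, rng))
    return out


@pytest.fixture(scope="session")
def two_topology_alignment():
    """2400-column alignment of 8 lineages: columns [0, 1200) evolved on
    one tree, [1200, 2400) on a maximally conflicting relabeling."""
    rng = np.random.default_rng(5)
    labs = [f"T{i}" for i in range(8)]
    t1 = ("((T0:0.02,T1:0.02):0.1,((T2:0.02,T3:0.02):0.1,"
          "((T4:0.02,T5:0.02):0.1,(T6:0.02,T7:0.02):0.1):0.05):0.05);")
    t2 = ("((T0:0.02,T7:0.02):0.1,((T2:0.02,T5:0.02):0.1,"
          "((T4:0.02,T1:0.02):0.1,(T6:0.02,T3:0.02):0.1):0.05):0.05);")
    anc = random_circle(rng, 2400)
    cfg = SimulationConfig()
    a1, _, _ = evolve_lineages(anc, t1, cfg, rng)
    a2, _, _ = evolve_lineages(anc, t2, cfg, rng)
    rows = tuple(
        a1.rows[a1.labels.index(l)][:1200] + a2.rows[a2.labels.index(l)][1200:]
        for l in labs
    )
    return st.MultipleAlignment(tuple(labs), rows), a1


def block_contrast(cm, crossover=1200):
    """Mean cross-block minus mean within-block compatibility entry."""
    k = len(cm.window_starts)
    w = cm.config.window
    within, cross = [], []
    for i, j in itertools.combinations(range(k), 2):
        si, sj = cm.window_starts[i], cm.window_starts[j]
        first = lambda s: s + w <= crossover
        second = lambda s: s >= crossover
        if (first(si) and second(sj)) or (first(sj) and second(si)):
            cross.append(cm.values[i, j])
        elif (first(si) and first(sj)) or (second(si) and second(sj)):
            within.append(cm.values[i, j])
    return float(np.mean(cross) - np.mean(within))
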