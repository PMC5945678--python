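"""Shared fixtures: small planted-truth datasets and derived networks."""

import numpy as np
import pandas as pd
import pytest

from bjnet import (
    SyntheticConfig,
    build_network,
    generate_dataset,
)
from bjnet.network import default_unsigned_power
from bjnet.modules import average_linkage, dynamic_tree_cut, module_eigengenes


def small_config(seed: int = 7, **overrides) -> SyntheticConfig:
    """Desk-scale variant of the study conditions used across tests."""
    params = dict(
        n_genes=600,
        module_sizes=[60] * 4,
        n_responsive=2,
        frac_preserved=0.5,
        rng_seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_data(small_cfg):
    """(expr_by_cultivar, design, go_map, tf_map, truth) at seed 7."""
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_networks(small_data):
    """TomNetwork per cultivar at the sample-size default power."""
    expr, _, _, _, _ = small_data
    nets = {}
    for cv, mat in expr.items():
        logm = mat.to_log2(1.0)
        keep = [g for g in logm.gene_ids if g != "BjUbq9"]
        logm = logm.subset_genes(keep)
        nets[cv] = build_network(logm, power=default_unsigned_power(logm.n_samples))
    return nets


@pytest.fixture(scope="session")
def small_partitions(small_networks):
    parts = {}
    for cv, net in small_networks.items():
        dend = average_linkage(net.dist_tom, net.gene_ids)
        parts[cv] = dynamic_tree_cut(dend, net.dist_tom, min_module_size=30, deep_split=2)
    return parts


@pytest.fixture(scope="session")
def small_eigengenes(small_data, small_partitions):
    expr, _, _, _, _ = small_data
    out = {}
    for cv, part in small_partitions.items():
        logm = expr[cv].to_log2(1.0).subset_genes(part.gene_ids)
        out[cv] = module_eigengenes(logm, part)
    return out


def truth_series(truth, cultivar: str) -> pd.Series:
    return pd.Series(truth.module_of[cultivar])


def match_planted(truth, cultivar, partition) -> dict:
    """Map planted module label -> recovered label by majority vote."""
    t = truth_series(truth, cultivar)
    mapping = {}
    for planted in sorted(set(t) - {"background"}):
        members = t.index[t == planted]
        labels = partition.labels.loc[[g for g in members if g in partition.labels.index]]
        if len(labels):
            mapping[planted] = labels.mode().iloc[0]
    return mapping


def random_symmetric_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a
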