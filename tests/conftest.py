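"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive: the brute-force FFL scan tests all
(tf, mirna, gene) triples directly against the raw edge sets, and the
Welch/BH oracle re-derives the t statistic and step-up correction from
first principles. They share no code with the implementation paths they
check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from fflnet import (COMPOSITE, FFLInstance, InteractionCatalog, MIRNA_FFL,
                    StageCandidates, TF_FFL)


def make_catalog(tf_gene=(), tf_mirna=(), mirna_gene=(), mirna_tf=()):
    cat = InteractionCatalog()
    cat.update("tf_to_gene", tf_gene)
    cat.update("tf_to_mirna", tf_mirna)
    cat.update("mirna_to_gene", mirna_gene)
    cat.update("mirna_to_tf", mirna_tf)
    return cat


def make_candidates(tfs, mirnas, genes, stage="S"):
    return StageCandidates(stage=stage, tfs=frozenset(tfs),
                           mirnas=frozenset(mirnas), genes=frozenset(genes))


def brute_force_ffls(candidates: StageCandidates,
                     catalog: InteractionCatalog) -> set[FFLInstance]:
    """Test every (tf, mirna, gene) triple directly against the edge sets."""
    out = set()
    for tf in candidates.tfs:
        for mirna in candidates.mirnas:
            for gene in candidates.genes:
                if (tf, gene) not in catalog.tf_to_gene:
                    continue
                if (mirna, gene) not in catalog.mirna_to_gene:
                    continue
                fwd = (tf, mirna) in catalog.tf_to_mirna
                rev = (mirna, tf) in catalog.mirna_to_tf
                if fwd and rev:
                    out.add(FFLInstance(tf, mirna, gene, COMPOSITE))
                elif fwd:
                    out.add(FFLInstance(tf, mirna, gene, TF_FFL))
                elif rev:
                    out.add(FFLInstance(tf, mirna, gene, MIRNA_FFL))
    return out


def random_catalog(rng: np.random.Generator, n_tf=5, n_mirna=5, n_gene=10,
                   density=0.3):
    """Random typed catalog with every edge type present independently."""
    tfs = [f"A{i}" for i in range(n_tf)]
    mirnas = [f"mir-{i}" for i in range(n_mirna)]
    genes = [f"g{i}" for i in range(n_gene)]
    cat = InteractionCatalog()
    for kind, srcs, tgts in (
        ("tf_to_gene", tfs, genes),
        ("tf_to_mirna", tfs, mirnas),
        ("mirna_to_gene", mirnas, genes),
        ("mirna_to_tf", mirnas, tfs),
    ):
        for s in srcs:
            for t in tgts:
                if rng.random() < density:
                    cat.add(kind, s, t)
    return make_candidates(tfs, mirnas, genes), cat


def welch_bh_oracle(a: np.ndarray, b: np.ndarray):
    """From-scratch Welch t-test p-values and BH step-up q-values."""
    from scipy.stats import t as t_dist

    p = np.empty(a.shape[0])
    for i in range(a.shape[0]):
        xa, xb = a[i], b[i]
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        na, nb = len(xa), len(xb)
        se2 = va / na + vb / nb
        diff = xa.mean() - xb.mean()
        if se2 == 0:
            p[i] = 1.0 if math.isclose(diff, 0.0, abs_tol=1e-12) else 0.0
            continue
        tstat = diff / math.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p[i] = 2 * t_dist.sf(abs(tstat), df)
    # Benjamini-Hochberg step-up from its definition
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * n / rank)
        q[idx] = running_min
    return p, q


@pytest.fixture
def rng():
    return np.random.default_rng(20150215)
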