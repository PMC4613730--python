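"""Synthetic regulatory data with planted feed-forward loops.

The generator emulates the *shape* of a literature-curated stage dataset —
typed regulator universes, sparse directed edge sets among candidate TFs,
miRNAs and genes, and a two-group log2 expression matrix with planted fold
changes — without any claim to biological content. Default sizes mirror a
single B-lineage stage transition: on the order of a dozen candidate TFs
and miRNAs and a few dozen candidate genes drawn from much larger
genome-background pools.

Planted motifs are injected by adding their defining edges on top of
independently drawn background edges; every planted triple uses a distinct
(TF, miRNA) pair (so planted motif types cannot collide) and a distinct
target gene (so unions of planted edges cannot close an unplanted triple).
With all background densities at zero the enumerator therefore returns
exactly the planted list; under background, planted triples remain
enumerable but a background reverse edge may upgrade a planted one-way
motif to composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._ids import GENE, MIRNA, TF
from .catalog import (EntityUniverse, ExpressionMatrix, InteractionCatalog,
                      StageCandidates)
from .ffl import COMPOSITE, FFLInstance, MIRNA_FFL, TF_FFL


@dataclass
class SyntheticConfig:
    """Sizes, densities, planted-motif counts and noise for one dataset.

    Defaults are scaled to one stage of lymphocyte maturation: candidate
    sets of 13 TFs / 11 miRNAs / 48 genes against background pools of a few
    hundred regulators, motif counts dominated by TF-FFLs, and a two-group
    expression screen of 1000 genes with 10 arrays per group, a planted
    log2 fold change of 2 and array-scale noise (sd 0.25 on log2).
    """

    # universe sizes
    n_tf: int = 200
    n_mirna: int = 150
    n_gene: int = 1000
    # candidate sizes
    n_tf_cand: int = 13
    n_mirna_cand: int = 11
    n_gene_cand: int = 48
    # background edge densities per type (fraction of possible pairs)
    d_tg: float = 0.15      # TF -> gene
    d_tm: float = 0.10      # TF -> miRNA
    d_mg: float = 0.15      # miRNA -> gene
    d_mt: float = 0.02      # miRNA -> TF
    # planted motif counts
    k_tf_ffl: int = 10
    k_mirna_ffl: int = 3
    k_composite: int = 1
    # where background edges live: only among candidates (the curated-data
    # shape) or across the whole universe (needed for exchangeable nulls)
    edge_scope: str = "candidates"
    # expression screen
    n_genes_expr: int = 1000
    n_per_group: int = 10
    planted_de_count: int = 50
    log2_fc: float = 2.0
    noise_sd: float = 0.25
    seed: int = 0
    stage: str = "S1"

    def __post_init__(self) -> None:
        for name in ("d_tg", "d_tm", "d_mg", "d_mt"):
            d = getattr(self, name)
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {d}")
        if self.edge_scope not in ("candidates", "universe"):
            raise ValueError(f"bad edge_scope: {self.edge_scope!r}")
        if (self.n_tf_cand > self.n_tf or self.n_mirna_cand > self.n_mirna
                or self.n_gene_cand > self.n_gene):
            raise ValueError("candidate sizes exceed universe sizes")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.planted_de_count > self.n_genes_expr:
            raise ValueError("more planted DE genes than genes")

    @property
    def k_total(self) -> int:
        return self.k_tf_ffl + self.k_mirna_ffl + self.k_composite


def _ids(prefix: str, n: int, width: int) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_dataset(config: SyntheticConfig,
                     ) -> tuple[EntityUniverse, StageCandidates,
                                InteractionCatalog, list[FFLInstance]]:
    """Draw one synthetic universe, candidate set, catalog and planted list.

    Background edges of each type are Bernoulli over the configured scope's
    regulator × target pairs; planted FFL edges are unioned on top. Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tfs = _ids("TF", config.n_tf, 4)
    mirnas = _ids("mir-", config.n_mirna, 4)
    genes = _ids("G", config.n_gene, 6)
    universe = EntityUniverse(
        tfs=frozenset(tfs), mirnas=frozenset(mirnas), genes=frozenset(genes))

    cand_tfs = sorted(str(t) for t in
                      rng.choice(tfs, config.n_tf_cand, replace=False))
    cand_mirnas = sorted(str(m) for m in
                         rng.choice(mirnas, config.n_mirna_cand,
                                    replace=False))
    cand_genes = sorted(str(g) for g in
                        rng.choice(genes, config.n_gene_cand, replace=False))
    candidates = StageCandidates(
        stage=config.stage,
        tfs=frozenset(cand_tfs),
        mirnas=frozenset(cand_mirnas),
        genes=frozenset(cand_genes),
    )

    if config.edge_scope == "candidates":
        scope_tfs, scope_mirnas, scope_genes = cand_tfs, cand_mirnas, cand_genes
    else:
        scope_tfs, scope_mirnas, scope_genes = tfs, mirnas, genes

    catalog = InteractionCatalog()
    for kind, sources, targets, density in (
        ("tf_to_gene", scope_tfs, scope_genes, config.d_tg),
        ("tf_to_mirna", scope_tfs, scope_mirnas, config.d_tm),
        ("mirna_to_gene", scope_mirnas, scope_genes, config.d_mg),
        ("mirna_to_tf", scope_mirnas, scope_tfs, config.d_mt),
    ):
        if density > 0 and sources and targets:
            mask = rng.random((len(sources), len(targets))) < density
            for i, j in zip(*np.nonzero(mask)):
                catalog.add(kind, sources[i], targets[j])

    planted = _plant_ffls(config, rng, cand_tfs, cand_mirnas, cand_genes,
                          catalog)
    return universe, candidates, catalog, planted


def _plant_ffls(config: SyntheticConfig, rng: np.random.Generator,
                cand_tfs: list[str], cand_mirnas: list[str],
                cand_genes: list[str],
                catalog: InteractionCatalog) -> list[FFLInstance]:
    k = config.k_total
    if k == 0:
        return []
    n_pairs = len(cand_tfs) * len(cand_mirnas)
    if k > n_pairs or k > len(cand_genes):
        raise ValueError(
            f"cannot plant {k} motifs on {n_pairs} distinct (TF, miRNA) "
            f"pairs and {len(cand_genes)} distinct genes")
    # distinct (tf, mirna) pairs keep planted types from colliding; distinct
    # genes keep planted-edge unions from closing unplanted triples
    pair_idx = rng.choice(n_pairs, size=k, replace=False)
    gene_idx = rng.choice(len(cand_genes), size=k, replace=False)
    types = ([TF_FFL] * config.k_tf_ffl + [MIRNA_FFL] * config.k_mirna_ffl
             + [COMPOSITE] * config.k_composite)
    planted = []
    for p, g, ffl_type in zip(pair_idx, gene_idx, types):
        tf = cand_tfs[p // len(cand_mirnas)]
        mirna = cand_mirnas[p % len(cand_mirnas)]
        gene = cand_genes[g]
        catalog.add("tf_to_gene", tf, gene)
        catalog.add("mirna_to_gene", mirna, gene)
        if ffl_type in (TF_FFL, COMPOSITE):
            catalog.add("tf_to_mirna", tf, mirna)
        if ffl_type in (MIRNA_FFL, COMPOSITE):
            catalog.add("mirna_to_tf", mirna, tf)
        planted.append(FFLInstance(tf, mirna, gene, ffl_type))
    return sorted(planted)


def generate_expression(config: SyntheticConfig,
                        ) -> tuple[ExpressionMatrix, list[str]]:
    """Two-group log2 expression matrix with planted fold changes.

    Intensity = per-gene baseline (uniform on [4, 12]) + group effect
    (``log2_fc`` added to group 2 for planted genes) + Gaussian noise.
    A distinct seed stream from :func:`generate_dataset` is used so the
    same config can feed both without coupling.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(1,)))
    genes = _ids("G", config.n_genes_expr, 6)
    n, m = config.n_genes_expr, config.n_per_group
    samples = [f"A{i+1}" for i in range(m)] + [f"B{i+1}" for i in range(m)]
    labels = pd.Series(["grp1"] * m + ["grp2"] * m, index=samples)

    baseline = rng.uniform(4.0, 12.0, size=n)
    planted_idx = np.sort(rng.choice(n, size=config.planted_de_count,
                                     replace=False))
    effect = np.zeros(n)
    effect[planted_idx] = config.log2_fc
    noise = rng.normal(0.0, config.noise_sd, size=(n, 2 * m))
    values = baseline[:, None] + noise
    values[:, m:] += effect[:, None]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        group_labels=labels,
    )
    return matrix, [genes[i] for i in planted_idx]


def write_fixture_dir(config: SyntheticConfig, out_dir: str | Path) -> None:
    """Write the full synthetic fixture set as TSV files.

    Produces candidates.tsv, universe.tsv, interactions.tsv,
    planted_ffls.tsv, expression.tsv, groups.tsv and planted_de_genes.tsv
    under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    universe, candidates, catalog, planted = generate_dataset(config)

    def _entity_frame(tfs, mirnas, genes) -> pd.DataFrame:
        rows = ([(t, TF) for t in sorted(tfs)]
                + [(m, MIRNA) for m in sorted(mirnas)]
                + [(g, GENE) for g in sorted(genes)])
        return pd.DataFrame(rows, columns=["identifier", "class"])

    _entity_frame(candidates.tfs, candidates.mirnas, candidates.genes
                  ).to_csv(out / "candidates.tsv", sep="\t", index=False)
    _entity_frame(universe.tfs, universe.mirnas, universe.genes
                  ).to_csv(out / "universe.tsv", sep="\t", index=False)
    catalog.write(out / "interactions.tsv")
    pd.DataFrame(
        [(config.stage, f.tf, f.mirna, f.gene, f.ffl_type) for f in planted],
        columns=["stage", "tf", "mirna", "gene", "ffl_type"],
    ).to_csv(out / "planted_ffls.tsv", sep="\t", index=False)

    expr, planted_de = generate_expression(config)
    expr.values.to_csv(out / "expression.tsv", sep="\t",
                       index_label="gene")
    pd.DataFrame({"sample": expr.group_labels.index,
                  "group": expr.group_labels.values}
                 ).to_csv(out / "groups.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": planted_de}).to_csv(
        out / "planted_de_genes.tsv", sep="\t", index=False)
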