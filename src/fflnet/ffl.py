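"""Feed-forward loop enumeration and classification.

An FFL here is a three-node motif on one TF, one miRNA and one joint target
gene: both regulators target the gene, and the regulators are linked in at
least one direction. The link direction names the master regulator and the
motif type:

* ``TF-FFL``       TF→miRNA only (plus TF→gene, miRNA→gene)
* ``miRNA-FFL``    miRNA→TF only
* ``composite``    mutual TF↔miRNA regulation

Mutual regulation is classified *only* as composite, so the three type
tallies partition the enumerated triples. The joint target must be a
candidate gene; loops closing on a TF (four-node structures) are out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalog import InteractionCatalog, StageCandidates

TF_FFL = "TF-FFL"
MIRNA_FFL = "miRNA-FFL"
COMPOSITE = "composite"
FFL_TYPES = (TF_FFL, MIRNA_FFL, COMPOSITE)


@dataclass(frozen=True, order=True)
class FFLInstance:
    """One classified (tf, mirna, gene) co-regulation triple."""

    tf: str
    mirna: str
    gene: str
    ffl_type: str

    def __post_init__(self) -> None:
        if self.ffl_type not in FFL_TYPES:
            raise ValueError(f"unknown FFL type: {self.ffl_type!r}")


@dataclass
class FFLSummary:
    """Per-stage FFL tallies and (optionally) permutation p-values."""

    stage: str
    n_tf_ffl: int
    n_mirna_ffl: int
    n_composite: int
    p_tf_perm: float | None = None
    p_mirna_perm: float | None = None

    @property
    def n_total(self) -> int:
        return self.n_tf_ffl + self.n_mirna_ffl + self.n_composite

    def with_p_values(self, p_tf: float, p_mirna: float) -> "FFLSummary":
        return replace(self, p_tf_perm=p_tf, p_mirna_perm=p_mirna)


def classify_pair(tf: str, mirna: str, catalog: InteractionCatalog,
                  ) -> str | None:
    """Motif type implied by the TF↔miRNA link, or None if unlinked."""
    fwd = (tf, mirna) in catalog.tf_to_mirna
    rev = (mirna, tf) in catalog.mirna_to_tf
    if fwd and rev:
        return COMPOSITE
    if fwd:
        return TF_FFL
    if rev:
        return MIRNA_FFL
    return None


def enumerate_ffls(candidates: StageCandidates,
                   catalog: InteractionCatalog) -> list[FFLInstance]:
    """Enumerate every FFL over the stage's candidate sets.

    A triple (tf, mirna, gene) qualifies when tf→gene, miRNA→gene and at
    least one TF↔miRNA edge are all in the catalog and all three nodes are
    stage candidates of the right class. Each qualifying triple appears
    exactly once, in (tf, mirna, gene) lexicographic order.
    """
    genes = candidates.genes
    tf_targets = {tf: set() for tf in candidates.tfs}
    for (tf, gene) in catalog.tf_to_gene:
        if tf in tf_targets and gene in genes:
            tf_targets[tf].add(gene)
    mirna_targets = {m: set() for m in candidates.mirnas}
    for (m, gene) in catalog.mirna_to_gene:
        if m in mirna_targets and gene in genes:
            mirna_targets[m].add(gene)

    out: list[FFLInstance] = []
    for tf in sorted(candidates.tfs):
        tg = tf_targets[tf]
        if not tg:
            continue
        for mirna in sorted(candidates.mirnas):
            ffl_type = classify_pair(tf, mirna, catalog)
            if ffl_type is None:
                continue
            for gene in sorted(tg & mirna_targets[mirna]):
                out.append(FFLInstance(tf, mirna, gene, ffl_type))
    return out


def summarize_ffls(ffls: Iterable[FFLInstance], stage: str) -> FFLSummary:
    """Tally the three motif types; p-value fields are left unset."""
    counts = {t: 0 for t in FFL_TYPES}
    for ffl in ffls:
        counts[ffl.ffl_type] += 1
    return FFLSummary(
        stage=stage,
        n_tf_ffl=counts[TF_FFL],
        n_mirna_ffl=counts[MIRNA_FFL],
        n_composite=counts[COMPOSITE],
    )


def ffls_to_frame(ffls: Sequence[FFLInstance], stage: str) -> pd.DataFrame:
    return pd.DataFrame(
        [(stage, f.tf, f.mirna, f.gene, f.ffl_type) for f in ffls],
        columns=["stage", "tf", "mirna", "gene", "ffl_type"],
    )


def write_ffls(ffls: Sequence[FFLInstance], stage: str,
               path: str | Path) -> None:
    ffls_to_frame(ffls, stage).to_csv(path, sep="\t", index=False)
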