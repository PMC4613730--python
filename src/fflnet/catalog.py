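"""Core data model: regulator universes, stage candidate sets, and the typed
interaction catalog, plus readers for the tab-delimited inputs.

The catalog holds four directed edge classes — TF→gene, TF→miRNA, miRNA→gene,
miRNA→TF — each pair labelled with its evidence (``verified`` > ``chip`` >
``predicted``). Genes never regulate anything in this model, and TF→TF or
miRNA→miRNA edges are rejected: feed-forward loops are defined on exactly one
TF, one miRNA and one joint target gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._ids import GENE, MIRNA, TF, normalize, parse_node_class

logger = logging.getLogger(__name__)

#: evidence labels, strongest first
EVIDENCE_LEVELS = ("verified", "chip", "predicted")
_EVIDENCE_RANK = {label: i for i, label in enumerate(EVIDENCE_LEVELS)}

#: the four typed edge classes, keyed by (regulator_class, target_class)
EDGE_KINDS = {
    (TF, GENE): "tf_to_gene",
    (TF, MIRNA): "tf_to_mirna",
    (MIRNA, GENE): "mirna_to_gene",
    (MIRNA, TF): "mirna_to_tf",
}


def _check_disjoint(tfs: frozenset, mirnas: frozenset, genes: frozenset) -> None:
    for a, b, names in (
        (tfs, mirnas, "TF/miRNA"),
        (tfs, genes, "TF/gene"),
        (mirnas, genes, "miRNA/gene"),
    ):
        overlap = a & b
        if overlap:
            raise ValueError(
                f"{names} sets overlap after normalization: {sorted(overlap)[:5]}"
            )


@dataclass(frozen=True)
class EntityUniverse:
    """Genome-background pools of TFs, miRNAs and genes.

    The TF and miRNA pools are the sampling populations of the permutation
    test, so each must contain every stage's candidate set of that class.
    """

    tfs: frozenset[str]
    mirnas: frozenset[str]
    genes: frozenset[str]

    def __post_init__(self) -> None:
        for s in (self.tfs, self.mirnas, self.genes):
            if any(not x for x in s):
                raise ValueError("empty identifier in universe")
        _check_disjoint(self.tfs, self.mirnas, self.genes)

    def class_of(self, identifier: str) -> str:
        if identifier in self.tfs:
            return TF
        if identifier in self.mirnas:
            return MIRNA
        if identifier in self.genes:
            return GENE
        raise KeyError(identifier)


@dataclass(frozen=True)
class StageCandidates:
    """Candidate TFs, miRNAs and genes for one developmental transition.

    ``stage`` is a free label; the six lymphocyte transitions are
    conventionally B1–B3 (pro-B→pre-B→immature→mature B) and T1–T3
    (DN→DP→CD4+/CD8+).
    """

    stage: str
    tfs: frozenset[str]
    mirnas: frozenset[str]
    genes: frozenset[str]

    def __post_init__(self) -> None:
        _check_disjoint(self.tfs, self.mirnas, self.genes)

    def check_universe(self, universe: EntityUniverse) -> None:
        """Require every candidate to belong to its universe pool."""
        for cand, pool, name in (
            (self.tfs, universe.tfs, "TF"),
            (self.mirnas, universe.mirnas, "miRNA"),
            (self.genes, universe.genes, "gene"),
        ):
            missing = cand - pool
            if missing:
                raise ValueError(
                    f"stage {self.stage}: {name} candidates absent from "
                    f"universe: {sorted(missing)[:5]}"
                )


class InteractionCatalog:
    """The four typed, evidence-labelled regulatory edge sets.

    Duplicate (regulator, target) pairs collapse to the strongest evidence
    label. Self-edges are impossible by construction (classes are disjoint)
    and rejected defensively.
    """

    def __init__(self) -> None:
        self.tf_to_gene: dict[tuple[str, str], str] = {}
        self.tf_to_mirna: dict[tuple[str, str], str] = {}
        self.mirna_to_gene: dict[tuple[str, str], str] = {}
        self.mirna_to_tf: dict[tuple[str, str], str] = {}

    def _edge_dict(self, kind: str) -> dict[tuple[str, str], str]:
        return getattr(self, kind)

    def add(self, kind: str, regulator: str, target: str,
            evidence: str = "predicted") -> None:
        if evidence not in _EVIDENCE_RANK:
            raise ValueError(f"unknown evidence label: {evidence!r}")
        if regulator == target:
            raise ValueError(f"self-edge rejected: {regulator}")
        edges = self._edge_dict(kind)
        pair = (regulator, target)
        prev = edges.get(pair)
        if prev is None or _EVIDENCE_RANK[evidence] < _EVIDENCE_RANK[prev]:
            edges[pair] = evidence

    def update(self, kind: str,
               edges: Iterable[tuple[str, str]] | Mapping[tuple[str, str], str],
               evidence: str = "predicted") -> None:
        if isinstance(edges, Mapping):
            for (reg, tgt), ev in edges.items():
                self.add(kind, reg, tgt, ev)
        else:
            for reg, tgt in edges:
                self.add(kind, reg, tgt, evidence)

    @property
    def n_edges(self) -> int:
        return (len(self.tf_to_gene) + len(self.tf_to_mirna)
                + len(self.mirna_to_gene) + len(self.mirna_to_tf))

    def regulators(self, node_class: str) -> set[str]:
        if node_class == TF:
            pairs: Iterable = list(self.tf_to_gene) + list(self.tf_to_mirna)
        elif node_class == MIRNA:
            pairs = list(self.mirna_to_gene) + list(self.mirna_to_tf)
        else:
            raise ValueError("genes do not regulate")
        return {reg for reg, _ in pairs}

    def to_frame(self) -> pd.DataFrame:
        """All edges as a tidy table (regulator, classes, target, evidence)."""
        rows = []
        for (rc, tc), kind in EDGE_KINDS.items():
            for (reg, tgt), ev in sorted(self._edge_dict(kind).items()):
                rows.append((reg, rc, tgt, tc, ev))
        return pd.DataFrame(
            rows,
            columns=["regulator", "regulator_class", "target",
                     "target_class", "evidence"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Two-group log2 expression intensities (genes × samples).

    ``values`` rows are genes, columns are samples; ``group_labels`` maps each
    sample to one of exactly two groups (the two adjacent developmental
    stages being compared).
    """

    values: pd.DataFrame
    group_labels: pd.Series

    def __post_init__(self) -> None:
        self.group_labels = self.group_labels.reindex(self.values.columns)
        if self.group_labels.isna().any():
            missing = self.values.columns[self.group_labels.isna()]
            raise ValueError(f"samples without group label: {list(missing)[:5]}")
        groups = self.groups
        if len(groups) != 2:
            raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
        counts = self.group_labels.value_counts()
        if (counts < 2).any():
            raise ValueError("each group needs >= 2 samples")
        if self.values.isna().any().any():
            raise ValueError("missing values in expression matrix")

    @property
    def groups(self) -> list[str]:
        return sorted(self.group_labels.unique())

    def group_columns(self, group: str) -> pd.DataFrame:
        return self.values.loc[:, self.group_labels == group]


# ---------------------------------------------------------------------------
# readers


def read_aliases(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping alias → canonical identifier.

    Used for explicit miRNA precursor/arm resolution; no fuzzy matching is
    ever applied beyond this table. Normalization is applied to both columns
    as miRNA identifiers when the value looks like one, else as symbols.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("alias table needs two columns (alias, canonical)")
    out: dict[str, str] = {}
    for alias, canon in zip(df.iloc[:, 0], df.iloc[:, 1]):
        a, c = str(alias).strip(), str(canon).strip()
        is_mirna = c.lower().startswith(("mir", "hsa-", "let-"))
        cls = MIRNA if is_mirna else TF
        out[normalize(a, cls)] = normalize(c, cls)
    return out


def _apply_alias(identifier: str, aliases: Mapping[str, str] | None) -> str:
    if aliases:
        return aliases.get(identifier, identifier)
    return identifier


def read_candidates(path: str | Path, stage: str,
                    aliases: Mapping[str, str] | None = None) -> StageCandidates:
    """Read a stage candidate list: TSV with columns (identifier, class).

    Class tokens are ``TF`` / ``miRNA`` / ``gene`` (case-insensitive).
    Duplicates collapse; an identifier claimed by two classes is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (identifier, class)")
    sets: dict[str, set[str]] = {TF: set(), MIRNA: set(), GENE: set()}
    seen: dict[str, str] = {}
    for lineno, (ident, cls_token) in enumerate(
            zip(df.iloc[:, 0], df.iloc[:, 1]), start=2):
        try:
            cls = parse_node_class(str(cls_token))
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from None
        ident = _apply_alias(normalize(str(ident), cls), aliases)
        if seen.setdefault(ident, cls) != cls:
            raise ValueError(
                f"{path}, line {lineno}: {ident!r} listed as both "
                f"{seen[ident]} and {cls}"
            )
        sets[cls].add(ident)
    return StageCandidates(
        stage=stage,
        tfs=frozenset(sets[TF]),
        mirnas=frozenset(sets[MIRNA]),
        genes=frozenset(sets[GENE]),
    )


def read_universe(path: str | Path,
                  aliases: Mapping[str, str] | None = None) -> EntityUniverse:
    """Read the genome-background universe (same TSV layout as candidates)."""
    cand = read_candidates(path, stage="__universe__", aliases=aliases)
    return EntityUniverse(tfs=cand.tfs, mirnas=cand.mirnas, genes=cand.genes)


def read_interactions(path: str | Path,
                      aliases: Mapping[str, str] | None = None,
                      ) -> InteractionCatalog:
    """Read the regulatory edge list.

    TSV columns: regulator, regulator_class, target, target_class, evidence.
    Rows with a gene regulator, or TF→TF / miRNA→miRNA, are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"regulator", "regulator_class", "target", "target_class",
                "evidence"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    catalog = InteractionCatalog()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rc = parse_node_class(str(row.regulator_class))
            tc = parse_node_class(str(row.target_class))
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from None
        if rc == GENE:
            raise ValueError(
                f"{path}, line {lineno}: genes cannot be regulators "
                f"({row.regulator})"
            )
        if (rc, tc) not in EDGE_KINDS:
            raise ValueError(
                f"{path}, line {lineno}: {rc}->{tc} edges are not part of "
                f"the co-regulation model"
            )
        reg = _apply_alias(normalize(str(row.regulator), rc), aliases)
        tgt = _apply_alias(normalize(str(row.target), tc), aliases)
        ev = str(row.evidence).strip().lower()
        if ev not in _EVIDENCE_RANK:
            raise ValueError(
                f"{path}, line {lineno}: unknown evidence label {ev!r}"
            )
        catalog.add(EDGE_KINDS[(rc, tc)], reg, tgt, ev)
    return catalog


def read_expression(path: str | Path, groups_path: str | Path,
                    ) -> ExpressionMatrix:
    """Read a genes × samples log2 matrix plus a sample→group TSV.

    Rows containing missing values are dropped with a warning before the
    matrix is validated.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    n_bad = int(values.isna().any(axis=1).sum())
    if n_bad:
        warnings.warn(f"dropping {n_bad} gene rows with missing values")
        values = values.dropna(axis=0)
    groups = pd.read_csv(groups_path, sep="\t", dtype=str)
    labels = pd.Series(groups.iloc[:, 1].values,
                       index=groups.iloc[:, 0].values)
    return ExpressionMatrix(values=values, group_labels=labels)


def read_tfbs(path: str | Path) -> pd.DataFrame:
    """Read a scored TFBS table: TSV columns (tf, gene, z)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected columns (tf, gene, z)")
    df = df.iloc[:, :3].copy()
    df.columns = ["tf", "gene", "z"]
    df["tf"] = [normalize(t, TF) for t in df["tf"]]
    df["gene"] = [normalize(g, GENE) for g in df["gene"]]
    df["z"] = pd.to_numeric(df["z"], errors="coerce").astype(float)
    df.loc[df["z"].isna(), "z"] = np.nan
    return df
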