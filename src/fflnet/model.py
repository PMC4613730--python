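"""Model/Results front end for one stage's co-regulation analysis.

`FFLCoRegulationModel` is built from a stage's candidate sets, the
interaction catalog and (optionally) the genome-background universe;
`fit()` enumerates the feed-forward loops, runs the two permutation
enrichment tests, assembles the stage network and detects hubs, returning
an `FFLCoRegulationResults` with a `summary()` table, tidy frames, file
writers and a permutation-histogram plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .catalog import (EntityUniverse, InteractionCatalog, StageCandidates,
                      read_candidates, read_interactions, read_universe)
from .enrichment import (PermutationResult, TAIL_ENRICHMENT,
                         run_both_permutations)
from .ffl import FFLInstance, FFLSummary, enumerate_ffls, ffls_to_frame, \
    summarize_ffls
from .network import (HubReport, StageNetwork, build_network, hub_report,
                      network_summary, write_network)


class FFLCoRegulationModel:
    """TF–miRNA–gene feed-forward-loop analysis of one stage.

    Parameters
    ----------
    candidates : StageCandidates
        The stage's candidate TFs, miRNAs and genes.
    catalog : InteractionCatalog
        The evidence-filtered regulatory edge sets.
    universe : EntityUniverse, optional
        Genome-background pools for the permutation test. When omitted, a
        degenerate universe equal to the candidates plus catalog regulators
        is used and enrichment p-values are uninformative.

    Examples
    --------
    >>> from fflnet import FFLCoRegulationModel, SyntheticConfig, generate_dataset
    >>> universe, cand, catalog, _ = generate_dataset(SyntheticConfig(seed=7))
    >>> res = FFLCoRegulationModel(cand, catalog, universe).fit(
    ...     n_perm=1000, seed=7)
    >>> res.ffl_summary.n_total == len(res.ffls)
    True
    """

    def __init__(self, candidates: StageCandidates,
                 catalog: InteractionCatalog,
                 universe: EntityUniverse | None = None) -> None:
        if universe is None:
            universe = EntityUniverse(
                tfs=candidates.tfs | frozenset(
                    catalog.regulators("TF")) - candidates.mirnas
                - candidates.genes,
                mirnas=candidates.mirnas | frozenset(
                    catalog.regulators("miRNA")) - candidates.tfs
                - candidates.genes,
                genes=candidates.genes,
            )
        candidates.check_universe(universe)
        self.candidates = candidates
        self.catalog = catalog
        self.universe = universe

    @classmethod
    def from_files(cls, candidates_path: str | Path,
                   interactions_path: str | Path,
                   stage: str,
                   universe_path: str | Path | None = None,
                   aliases=None) -> "FFLCoRegulationModel":
        """Build a model from candidate/interaction (and universe) TSVs."""
        candidates = read_candidates(candidates_path, stage, aliases=aliases)
        catalog = read_interactions(interactions_path, aliases=aliases)
        universe = (read_universe(universe_path, aliases=aliases)
                    if universe_path else None)
        return cls(candidates, catalog, universe)

    def fit(self, n_perm: int = 10000, seed: int | None = None,
            pseudocount: int = 0, tail: str = TAIL_ENRICHMENT,
            max_hubs: int = 5) -> "FFLCoRegulationResults":
        """Enumerate FFLs, test enrichment, assemble the network, rank hubs."""
        ffls = enumerate_ffls(self.candidates, self.catalog)
        summary = summarize_ffls(ffls, self.candidates.stage)
        perm_tf = perm_mirna = None
        if n_perm > 0:
            perm_tf, perm_mirna = run_both_permutations(
                self.candidates, self.catalog, self.universe,
                n_perm=n_perm, seed=seed, pseudocount=pseudocount, tail=tail)
            summary = summary.with_p_values(perm_tf.p_value,
                                            perm_mirna.p_value)
        network = build_network(ffls, self.candidates.stage)
        hubs = hub_report(network, ffls, max_hubs=max_hubs,
                          catalog=self.catalog)
        return FFLCoRegulationResults(
            model=self, ffls=ffls, ffl_summary=summary, network=network,
            hubs=hubs, perm_tf=perm_tf, perm_mirna=perm_mirna)


@dataclass
class FFLCoRegulationResults:
    """Fitted per-stage results: motifs, enrichment, network and hubs."""

    model: FFLCoRegulationModel
    ffls: list[FFLInstance]
    ffl_summary: FFLSummary
    network: StageNetwork
    hubs: HubReport
    perm_tf: PermutationResult | None
    perm_mirna: PermutationResult | None

    @property
    def stage(self) -> str:
        return self.model.candidates.stage

    def ffl_frame(self) -> pd.DataFrame:
        return ffls_to_frame(self.ffls, self.stage)

    def summary_frame(self) -> pd.DataFrame:
        s = self.ffl_summary
        n_edges, n_mirna, n_tf, n_gene = network_summary(self.network)
        return pd.DataFrame([{
            "stage": s.stage,
            "n_tf_ffl": s.n_tf_ffl,
            "n_mirna_ffl": s.n_mirna_ffl,
            "n_composite": s.n_composite,
            "p_tf_perm": s.p_tf_perm,
            "p_mirna_perm": s.p_mirna_perm,
            "net_edges": n_edges,
            "net_mirnas": n_mirna,
            "net_tfs": n_tf,
            "net_genes": n_gene,
        }])

    def permutation_frame(self) -> pd.DataFrame:
        rows = []
        for res in (self.perm_tf, self.perm_mirna):
            if res is not None:
                rows.append((self.stage, res.which, res.observed_count,
                             res.n_perm, res.p_value, res.seed))
        return pd.DataFrame(
            rows, columns=["stage", "which", "observed", "n_perm",
                           "p_value", "seed"])

    def summary(self) -> str:
        """Human-readable per-stage report (motif counts, p-values, hubs)."""
        s = self.ffl_summary
        n_edges, n_mirna, n_tf, n_gene = network_summary(self.network)
        lines = [
            f"FFL co-regulation analysis — stage {self.stage}",
            "=" * 48,
            f"Candidates: {len(self.model.candidates.tfs)} TFs, "
            f"{len(self.model.candidates.mirnas)} miRNAs, "
            f"{len(self.model.candidates.genes)} genes",
            f"FFLs: {s.n_tf_ffl} TF-FFL / {s.n_mirna_ffl} miRNA-FFL / "
            f"{s.n_composite} composite (total {s.n_total})",
        ]
        if s.p_tf_perm is not None:
            lines.append(
                f"Permutation p: TF axis {s.p_tf_perm:.4g}, "
                f"miRNA axis {s.p_mirna_perm:.4g} "
                f"(n_perm={self.perm_tf.n_perm})")
        lines += [
            f"Network: {n_edges} edges, {n_mirna} miRNAs, {n_tf} TFs, "
            f"{n_gene} genes",
            f"Hub TFs: {', '.join(self.hubs.hub_tfs) or '(none)'}",
            f"Hub miRNAs: {', '.join(self.hubs.hub_mirnas) or '(none)'}",
            "Hub pairs: " + (", ".join(
                f"{tf}|{m} ({n}{'*' if mut else ''})"
                for tf, m, n, mut in self.hubs.hub_pairs) or "(none)"),
        ]
        if any(mut for *_, mut in self.hubs.hub_pairs):
            lines.append("  (* mutual TF-miRNA regulation)")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write ffls.tsv, ffl_summary.tsv, permutation.tsv, network.graphml
        and hubs.tsv under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.ffl_frame().to_csv(out / "ffls.tsv", sep="\t", index=False)
        self.summary_frame().to_csv(out / "ffl_summary.tsv", sep="\t",
                                    index=False)
        self.permutation_frame().to_csv(out / "permutation.tsv", sep="\t",
                                        index=False)
        write_network(self.network, out / "network.graphml", "graphml")
        self.hubs.to_frame().to_csv(out / "hubs.tsv", sep="\t", index=False)

    def plot_permutation(self, which: str = "TF", ax=None):
        """Histogram of permuted FFL totals with the observed count marked."""
        import matplotlib.pyplot as plt

        res = self.perm_tf if which == "TF" else self.perm_mirna
        if res is None:
            raise ValueError("no permutation results (fit with n_perm > 0)")
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(res.perm_counts, bins=30, color="steelblue", alpha=0.8)
        ax.axvline(res.observed_count, color="firebrick", lw=2,
                   label=f"observed = {res.observed_count}")
        ax.set_xlabel(f"total FFLs under {which} resampling")
        ax.set_ylabel("permutations")
        ax.set_title(f"{self.stage}: p = {res.p_value:.4g} "
                     f"(n={res.n_perm})")
        ax.legend()
        return ax
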