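"""Refinement of externally predicted miRNA-target pairs.

Running the eleven target-prediction programs is out of scope: their votes
arrive as a table. A pair survives when at least five programs predict it
AND the gene's measured expression change opposes the miRNA's direction by
more than 1.5-fold ("inverse correlation" used operationally as
sign-opposition against one tumor line, not a correlation coefficient).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

# the default program universe integrated by miRecords
DEFAULT_PROGRAMS = (
    "DIANA-microT",
    "MicroInspector",
    "miRanda",
    "MirTarget2",
    "miTarget",
    "NBmiRTar",
    "PicTar",
    "PITA",
    "RNA22",
    "RNAhybrid",
    "TargetScan",
)

DEFAULT_MIN_PROGRAMS = 5
DEFAULT_GENE_FC_THRESHOLD = 1.5


@dataclass(frozen=True)
class TargetVote:
    gene: str
    mirna: str
    programs: frozenset[str]


@dataclass(frozen=True)
class GeneExpressionChange:
    gene: str
    fold_change: float  # signed ratio vs normal (e.g. -1.79 for 1.79-fold down)

    def direction(self, threshold: float = DEFAULT_GENE_FC_THRESHOLD) -> str:
        if self.fold_change > threshold:
            return "up"
        if self.fold_change < -threshold:
            return "down"
        return "unchanged"


def _norm_gene(gene: str) -> str:
    return gene.strip().upper()


def load_votes(
    table: pd.DataFrame,
    universe: Sequence[str] = DEFAULT_PROGRAMS,
) -> list[TargetVote]:
    """Build vote records from a long-format table (gene, mirna, program).

    A program name outside the configured universe is an error naming it.
    """
    allowed = set(universe)
    grouped: dict[tuple[str, str], set[str]] = defaultdict(set)
    for _, row in table.iterrows():
        prog = str(row["program"]).strip()
        if prog not in allowed:
            raise ValueError(f"unknown prediction program {prog!r}")
        grouped[(_norm_gene(row["gene"]), str(row["mirna"]).strip())].add(prog)
    return [
        TargetVote(gene, mirna, frozenset(progs))
        for (gene, mirna), progs in sorted(grouped.items())
    ]


def vote_filter(
    votes: Iterable[TargetVote], min_programs: int = DEFAULT_MIN_PROGRAMS
) -> list[TargetVote]:
    """List A: pairs predicted by at least min_programs programs."""
    return [v for v in votes if len(v.programs) >= min_programs]


def inverse_correlation_filter(
    list_a: Iterable[TargetVote],
    mirna_directions: Mapping[str, str],
    gene_changes: Mapping[str, GeneExpressionChange] | Iterable[GeneExpressionChange],
    gene_fc_threshold: float = DEFAULT_GENE_FC_THRESHOLD,
) -> tuple[list[TargetVote], dict[str, int]]:
    """Keep pairs where gene and miRNA move in opposite directions.

    miRNA down & gene up, or miRNA up & gene down, with the gene change
    exceeding the threshold. Pairs whose gene is absent from the expression
    table (or whose miRNA is not differentially expressed) are dropped and
    counted.
    """
    if not isinstance(gene_changes, Mapping):
        gene_changes = {c.gene: c for c in gene_changes}
    gene_changes = {_norm_gene(g): c for g, c in gene_changes.items()}
    kept: list[TargetVote] = []
    dropped = {"gene_missing": 0, "mirna_not_de": 0, "concordant_or_flat": 0}
    for vote in list_a:
        mdir = mirna_directions.get(vote.mirna)
        if mdir is None:
            dropped["mirna_not_de"] += 1
            continue
        change = gene_changes.get(_norm_gene(vote.gene))
        if change is None:
            dropped["gene_missing"] += 1
            continue
        gdir = change.direction(gene_fc_threshold)
        if (mdir, gdir) in (("down", "up"), ("up", "down")):
            kept.append(vote)
        else:
            dropped["concordant_or_flat"] += 1
    return kept, dropped


def multi_target_report(
    final_targets: Iterable[TargetVote], min_mirnas: int = 3
) -> dict[str, list[str]]:
    """Genes targeted by at least min_mirnas differentially regulated miRNAs."""
    per_gene: dict[str, set[str]] = defaultdict(set)
    for vote in final_targets:
        per_gene[_norm_gene(vote.gene)].add(vote.mirna)
    return {
        gene: sorted(mirnas)
        for gene, mirnas in sorted(per_gene.items())
        if len(mirnas) >= min_mirnas
    }


def host_gene_concordance(
    intronic_mirna_directions: Mapping[str, str],
    host_map: Mapping[str, str],
    host_changes: Mapping[str, GeneExpressionChange],
    gene_fc_threshold: float = DEFAULT_GENE_FC_THRESHOLD,
) -> tuple[pd.DataFrame, float, int]:
    """Concordance of intronic miRNAs with their host transcripts.

    Per pair: both_up / both_down / discordant; returns the table, the
    concordant fraction, and the number of pairs skipped for missing host
    expression.
    """
    host_changes = {_norm_gene(g): c for g, c in host_changes.items()}
    rows = []
    skipped = 0
    for mirna, mdir in sorted(intronic_mirna_directions.items()):
        host = host_map.get(mirna)
        if host is None:
            skipped += 1
            continue
        change = host_changes.get(_norm_gene(host))
        if change is None:
            skipped += 1
            continue
        hdir = change.direction(gene_fc_threshold)
        if mdir == hdir == "up":
            status = "both_up"
        elif mdir == hdir == "down":
            status = "both_down"
        else:
            status = "discordant"
        rows.append((mirna, host, mdir, hdir, status))
    table = pd.DataFrame(
        rows, columns=["mirna", "host", "mirna_direction", "host_direction", "status"]
    )
    if len(table):
        concordant = float((table["status"] != "discordant").mean())
    else:
        concordant = float("nan")
    return table, concordant, skipped
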