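"""Deterministic text reports: substitution TSV, run manifest, profile table.

Outputs are byte-stable for identical inputs (the run manifest carries the
only timestamp, and re-running with the manifest's recorded parameters must
reproduce the TSV and FASTA outputs exactly).
"""

from __future__ import annotations

import datetime
from typing import Iterable, List, Mapping, Sequence, Tuple

from .design import DesignResult, RankedHomolog, VariationProfile

REPORT_VERSION = 1

_REPORT_COLUMNS = (
    "position", "from", "to", "donor_id", "donor_identity_pct",
    "donor_similarity_pct", "donor_rank", "override", "status",
)


def render_report(result: DesignResult) -> str:
    """Substitution report: one row per target position, TSV."""
    lines = [f"# orthoswap substitution report v{REPORT_VERSION}"]
    lines.append("\t".join(_REPORT_COLUMNS))
    for cluster_result in result.clusters:
        subs = {s.position: s for s in cluster_result.substitutions}
        donor = cluster_result.suggestion
        for pos in sorted(cluster_result.cluster):
            sub = subs.get(pos)
            if sub is None:
                lines.append("\t".join([
                    str(pos), result.target.forbidden_residue, ".",
                    ".", ".", ".", ".", "no", "UNRESOLVED",
                ]))
                continue
            if sub.override:
                donor_id, ident, sim, rank = "user", ".", ".", "."
            else:
                donor_id = donor.source_id
                ident = f"{donor.source_identity_pct:.1f}"
                sim = f"{donor.source_similarity_pct:.1f}"
                rank = str(donor.source_rank)
            lines.append("\t".join([
                str(pos), sub.from_residue, sub.to_residue,
                donor_id, ident, sim, rank,
                "yes" if sub.override else "no", "OK",
            ]))
    return "\n".join(lines) + "\n"


def render_ranking(ranked: Sequence[RankedHomolog]) -> str:
    """Homolog ranking table, TSV."""
    lines = ["rank\thit_id\tscore\tidentity_pct\tsimilarity_pct\t"
             "query_start\tquery_end\thit_start\thit_end"]
    for hom in ranked:
        a = hom.alignment
        lines.append("\t".join([
            str(hom.rank), a.hit_id, f"{a.score:g}",
            f"{a.identity_pct:.1f}", f"{a.similarity_pct:.1f}",
            str(a.query_start), str(a.query_end), str(a.hit_start), str(a.hit_end),
        ]))
    return "\n".join(lines) + "\n"


def render_profile(profile: VariationProfile) -> str:
    """Variation profile: ranked homologs as rows, positions as columns,
    followed by per-position residue tallies."""
    header = ["rank", "source_id", "identity_pct"] + [
        f"pos{p}" for p in profile.positions
    ]
    lines = ["\t".join(header)]
    for row in profile.rows:
        cells = [str(row.rank), row.source_id, f"{row.identity_pct:.1f}"]
        cells += [row.mapped[p].token() for p in profile.positions]
        lines.append("\t".join(cells))
    lines.append("")
    for pos in profile.positions:
        tally = profile.tally(pos)
        rendered = ",".join(
            f"{res}:{count}" for res, count in sorted(
                tally.items(), key=lambda kv: (-kv[1], kv[0])
            )
        )
        lines.append(f"# tally pos{pos}\t{rendered}")
    return "\n".join(lines) + "\n"


def render_manifest(entries: Iterable[Tuple[str, object]]) -> str:
    """Plain key = value manifest, in the given order."""
    return "".join(f"{key} = {value}\n" for key, value in entries)


def manifest_entries(
    version: str,
    params,
    extra: Mapping[str, object],
) -> List[Tuple[str, object]]:
    """Standard manifest preamble: tool version, timestamp, alignment params."""
    entries: List[Tuple[str, object]] = [
        ("tool", "orthoswap"),
        ("version", version),
        ("timestamp", datetime.datetime.now(datetime.timezone.utc).isoformat()),
        ("matrix", params.matrix.name),
        ("gap_open", params.gap_open),
        ("gap_extend", params.gap_extend),
    ]
    entries.extend(extra.items())
    return entries
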