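"""Greedy identity-based redundancy reduction.

Curated study sets keep only one representative of any group of
near-identical sequences; here a record is dropped when its global
pairwise identity with an already-kept representative exceeds the
threshold (default 0.90, i.e. strictly above 90%).  Identity is
computed over residue–residue alignment columns, the least
length-biased of the common conventions.  Records are visited longest
first (ties broken by accession) so representatives are deterministic
and information-rich.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .aligner import DEFAULT_PARAMS, AlignParams, pairwise_align, percent_identity
from .seqio import SequenceRecord


@dataclass(frozen=True)
class IdentityResult:
    accession_a: str
    accession_b: str
    identity: float
    aligned_columns: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")


def pairwise_identity(
    a: SequenceRecord, b: SequenceRecord, params: AlignParams = DEFAULT_PARAMS
) -> IdentityResult:
    """Global-alignment identity between two records.

    The denominator counts alignment columns where both rows carry a
    residue; terminal and internal gap columns are excluded.
    """
    ga, gb, _ = pairwise_align(a, b, params)
    ident, comparable = percent_identity(ga, gb)
    return IdentityResult(
        accession_a=a.accession,
        accession_b=b.accession,
        identity=ident,
        aligned_columns=comparable,
    )


def dedupe(
    records: list[SequenceRecord],
    threshold: float = 0.90,
    params: AlignParams = DEFAULT_PARAMS,
) -> tuple[list[SequenceRecord], dict[str, list[str]]]:
    """Greedy redundancy filter at a pairwise-identity threshold.

    Returns ``(kept, clusters)`` where ``clusters`` maps each kept
    representative's accession to its member accessions (representative
    first).  A record joins the first representative whose identity with
    it is strictly above the threshold; otherwise it is kept itself.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.residues), r.accession))
    kept: list[SequenceRecord] = []
    clusters: dict[str, list[str]] = {}
    for rec in ordered:
        home = None
        for rep in kept:
            if pairwise_identity(rep, rec, params).identity > threshold:
                home = rep.accession
                break
        if home is None:
            kept.append(rec)
            clusters[rec.accession] = [rec.accession]
        else:
            clusters[home].append(rec.accession)
    # restore input order among the kept records
    kept_acc = {r.accession for r in kept}
    kept_in_order = [r for r in records if r.accession in kept_acc]
    return kept_in_order, clusters


def write_cluster_report(clusters: dict[str, list[str]], path: str | Path) -> None:
    """Tab-separated cluster report: representative, size, members."""
    with open(path, "w", newline="\n") as fh:
        fh.write("representative\tsize\tmembers\n")
        for rep, members in clusters.items():
            fh.write(f"{rep}\t{len(members)}\t{','.join(members)}\n")
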