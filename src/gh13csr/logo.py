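"""Position frequency matrices, information content and consensus.

These are the numbers behind a sequence logo: per fingerprint column,
residue counts over the 20-letter alphabet, Shannon information
content in bits (``log2(20) - H``, optionally with the small-sample
correction ``e_n = 19 / (2 ln 2 n)``) and the consensus letter.  Gaps
and ``X`` are excluded from the counts.  One profile set is computed
per subfamily plus one pooled over everything, mirroring the
seven-logo view of a six-subfamily study set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .csr import Fingerprint
from .seqio import AMINO_ACIDS

MAX_BITS = math.log2(len(AMINO_ACIDS))


@dataclass(frozen=True)
class PositionProfile:
    """Counts and summary statistics for one fingerprint column."""

    position: int
    counts: dict[str, int]
    total: int
    information_bits: float
    consensus: str
    all_gap: bool = False


def information_content(
    counts: dict[str, int], small_sample_correction: bool = False
) -> float:
    """Shannon information of a column in bits.

    ``log2(20) - H`` with ``H = -sum p log2 p`` over the observed
    letters; all-gap columns report 0.  The optional correction
    subtracts ``e_n = 19 / (2 ln 2 n)`` (clipped at zero).
    """
    total = sum(counts.values())
    if total == 0:
        return 0.0
    entropy = 0.0
    for c in counts.values():
        if c:
            p = c / total
            entropy -= p * math.log2(p)
    ic = MAX_BITS - entropy
    if small_sample_correction:
        ic -= (len(AMINO_ACIDS) - 1) / (2 * math.log(2) * total)
    return max(ic, 0.0)


def column_frequencies(
    fingerprints: list[Fingerprint], small_sample_correction: bool = False
) -> list[PositionProfile]:
    """One :class:`PositionProfile` per fingerprint column.

    Consensus is the most frequent letter (alphabetical tie-break);
    all-gap columns get zero total, consensus ``'-'`` and a flag.
    """
    if not fingerprints:
        raise ValueError("no fingerprints given")
    width = len(fingerprints[0].sequence)
    profiles = []
    for j in range(width):
        counts = {aa: 0 for aa in AMINO_ACIDS}
        for fp in fingerprints:
            ch = fp.sequence[j]
            if ch in counts:
                counts[ch] += 1
        total = sum(counts.values())
        if total == 0:
            profiles.append(
                PositionProfile(j + 1, counts, 0, 0.0, "-", all_gap=True)
            )
            continue
        best = max(counts.values())
        consensus = min(aa for aa, c in counts.items() if c == best)
        profiles.append(
            PositionProfile(
                position=j + 1,
                counts=counts,
                total=total,
                information_bits=information_content(counts, small_sample_correction),
                consensus=consensus,
            )
        )
    return profiles


def consensus_string(profiles: list[PositionProfile]) -> str:
    return "".join(p.consensus for p in profiles)


def subfamily_logos(
    fingerprints: list[Fingerprint], small_sample_correction: bool = False
) -> dict[str, list[PositionProfile]]:
    """Profile sets per subfamily plus the pooled set under key ``"all"``.

    With all six subfamilies present this yields seven profile sets.
    """
    groups: dict[str, list[Fingerprint]] = {}
    for fp in fingerprints:
        groups.setdefault(fp.subfamily, []).append(fp)
    out = {"all": column_frequencies(fingerprints, small_sample_correction)}
    for label in sorted(groups):
        out[label] = column_frequencies(groups[label], small_sample_correction)
    return out


def write_profile_table(
    logos: dict[str, list[PositionProfile]], path: str | Path
) -> None:
    """Tab-separated profile matrix across all groups."""
    letters = list(AMINO_ACIDS)
    with open(path, "w", newline="\n") as fh:
        fh.write("group\tposition\t" + "\t".join(letters) + "\ttotal\tbits\tconsensus\n")
        for group in logos:
            for p in logos[group]:
                row = "\t".join(str(p.counts[aa]) for aa in letters)
                fh.write(
                    f"{group}\t{p.position}\t{row}\t{p.total}\t"
                    f"{p.information_bits:.4f}\t{p.consensus}\n"
                )
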