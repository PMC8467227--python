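"""Synthetic GH13-like families with planted ground truth.

Every downstream stage of the pipeline (alignment, CSR extraction,
logo statistics, chloride classification, SBS mapping, trees) is
exercised against families generated here, so no database download is
ever needed.  A family is built from a per-subfamily consensus: eight
CSR motifs at the fixed layout widths carrying the catalytic triad
(D28/E37/D46) and, when requested, the chloride triad (R26/N44 plus
R or K at position 50), joined by variable-length linkers drawn from a
family-wide consensus.  Point substitutions hit linker positions (and,
optionally, non-landmark CSR positions) at a configurable rate;
landmark residues and planted SBS aromatics are never mutated.

The generator emulates the statistical structure of a curated
subfamily alignment — conserved blocks over a noisy background — not
its evolutionary history: there is no substitution-model evolution
along a tree and no indels inside CSRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .csr import DEFAULT_LAYOUT, CsrLayout, Fingerprint
from .registry import CSR_SEQUENCE_ORDER, ReferenceAnnotation, SbsResidue, SbsSite, SbsTemplate
from .seqio import AMINO_ACIDS, GAP, Msa, SequenceRecord

#: Default consensus CSR motifs per subfamily.  Landmark offsets encode the
#: documented residues: R at fingerprint 26, D at 28 (CSR-II), E at 37
#: (CSR-III), N at 44 and D at 46 (CSR-IV); position 50 (CSR-VII) is set by
#: the chloride-triad option.  All remaining letters are fixed arbitrary
#: choices that differ between subfamilies, which is all the downstream
#: statistics need.
DEFAULT_MOTIFS: dict[str, dict[str, str]] = {
    "GH13_1": {
        "CSR-VIII": "GFS",
        "CSR-VI": "GVTHVWLPP",
        "CSR-I": "DVVANH",
        "CSR-V": "LLDLA",
        "CSR-II": "GFRIDAAKH",
        "CSR-III": "YQIIEVLD",
        "CSR-IV": "FVDNHD",
        "CSR-VII": "GVPQIYYGD",
    },
    "GH13_5": {
        "CSR-VIII": "ANT",
        "CSR-VI": "GITHVWLPA",
        "CSR-I": "DVVLNH",
        "CSR-V": "VLDVA",
        "CSR-II": "GFRIDAVKH",
        "CSR-III": "YQILEVLD",
        "CSR-IV": "FVDNHD",
        "CSR-VII": "GTPAIYYGD",
    },
    "GH13_15": {
        "CSR-VIII": "QFA",
        "CSR-VI": "GVTAVWISP",
        "CSR-I": "DAVINH",
        "CSR-V": "ILDFA",
        "CSR-II": "GFRIDAAKH",
        "CSR-III": "FQIVEVLD",
        "CSR-IV": "FVDNHD",
        "CSR-VII": "GSPRVYYGT",
    },
    "GH13_24": {
        "CSR-VIII": "QVL",
        "CSR-VI": "GVTAVWISP",
        "CSR-I": "DAVANH",
        "CSR-V": "LMDFV",
        "CSR-II": "GFRIDASKH",
        "CSR-III": "FQEVEVLD",
        "CSR-IV": "FVDNHD",
        "CSR-VII": "GFPRVYYGT",
    },
    "GH13_32": {
        "CSR-VIII": "GIT",
        "CSR-VI": "GITHLWLPP",
        "CSR-I": "DVVFNH",
        "CSR-V": "LIDLV",
        "CSR-II": "GFRIDTAKH",
        "CSR-III": "YQIVEVLD",
        "CSR-IV": "FVDNHD",
        "CSR-VII": "GQPSIYYGS",
    },
    "GH13_42": {
        "CSR-VIII": "MTA",
        "CSR-VI": "GVTHIWLPA",
        "CSR-I": "DVVTNH",
        "CSR-V": "TLDVV",
        "CSR-II": "GFRIDAAKH",
        "CSR-III": "YQISEVLD",
        "CSR-IV": "FVSNHD",
        "CSR-VII": "GVPQIHYYG",
    },
}

#: Subfamilies whose members are chloride-activated by default.
_DEFAULT_TRIAD = {"GH13_15": "RNR", "GH13_24": "RNR"}

_TRIAD_THIRD = {"RNR": "R", "RNK": "K", "none": "Q"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic family.

    ``substitution_rate`` is the per-position probability that a linker
    (or, with ``protect_csr=False``, a non-landmark CSR) residue is
    replaced by a uniformly random different amino acid.
    ``sbs_plant`` lists planted surface-site aromatics as
    ``(linker_index, offset, letter)`` with 0-based linker index (seven
    inter-CSR linkers) and 0-based offset within the linker; planted
    offsets must fall below the linker's minimum length so every record
    carries them.
    """

    subfamily: str = "GH13_24"
    n_sequences: int = 60
    csr_motifs: dict[str, str] | None = None
    linker_length_ranges: tuple[tuple[int, int], ...] = ((4, 12),) * 7
    substitution_rate: float = 0.05
    protect_csr: bool = True
    chloride_triad: str | None = None  # None -> subfamily default
    sbs_plant: tuple[tuple[int, int, str], ...] = ()
    signal_peptide_length: int = 0
    c_tail_length: int = 0
    seed: int = 0
    accession_prefix: str = "SYN"

    def resolved_triad(self) -> str:
        if self.chloride_triad is not None:
            return self.chloride_triad
        return _DEFAULT_TRIAD.get(self.subfamily, "none")

    def resolved_motifs(self, layout: CsrLayout = DEFAULT_LAYOUT) -> dict[str, str]:
        triad = self.resolved_triad()
        if triad not in ("RNR", "RNK", "none", "custom"):
            raise ValueError(f"unknown chloride_triad option {triad!r}")
        motifs = dict(self.csr_motifs or DEFAULT_MOTIFS[self.subfamily])
        for name in layout.order:
            if name not in motifs:
                raise ValueError(f"missing CSR motif {name}")
            if len(motifs[name]) != layout.width(name):
                raise ValueError(
                    f"motif {name} has length {len(motifs[name])}, layout "
                    f"requires {layout.width(name)}"
                )
        if triad != "custom":
            span = layout.span("CSR-VII")
            off = layout.chloride_arg_lys - span.start
            vii = motifs["CSR-VII"]
            motifs["CSR-VII"] = vii[:off] + _TRIAD_THIRD[triad] + vii[off + 1 :]
        return motifs

    def validate(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")
        if len(self.linker_length_ranges) != 7:
            raise ValueError("exactly 7 inter-CSR linker ranges are required")
        for i, (lo, hi) in enumerate(self.linker_length_ranges):
            if lo < 0 or hi < lo:
                raise ValueError(f"linker range {i}: need 0 <= min <= max")
        for g, off, letter in self.sbs_plant:
            if not 0 <= g < 7:
                raise ValueError(f"sbs_plant linker index {g} outside 0..6")
            lo, _ = self.linker_length_ranges[g]
            if not 0 <= off < lo:
                raise ValueError(
                    f"sbs_plant offset {off} must fall below linker {g} minimum "
                    f"length {lo} so all records carry it"
                )
            if letter not in "FWY":
                raise ValueError(f"sbs_plant letter {letter!r} is not aromatic")
        self.resolved_motifs()


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one generated sequence."""

    accession: str
    subfamily: str
    fingerprint: str
    csr_starts: dict[str, int]           # 1-based, ungapped
    triad_positions: tuple[int, int, int]
    chloride_capable: bool
    sbs_positions: tuple[tuple[int, str], ...]  # 1-based ungapped (pos, letter)
    linker_lengths: tuple[int, ...]
    signal_length: int
    tail_length: int


def _mutate(
    seq: list[str],
    protected: set[int],
    rate: float,
    rng: np.random.Generator,
) -> None:
    if rate <= 0.0:
        return
    for i in range(len(seq)):
        if i in protected:
            continue
        if rng.random() < rate:
            current = seq[i]
            choices = [a for a in AMINO_ACIDS if a != current]
            seq[i] = choices[rng.integers(len(choices))]


def generate_family(
    config: SyntheticConfig, layout: CsrLayout = DEFAULT_LAYOUT
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Generate a family and its truth table, deterministically per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    motifs = config.resolved_motifs(layout)
    order = layout.order
    aa = list(AMINO_ACIDS)

    # family-wide consensus pieces (drawn once, shared by all records)
    consensus_linkers = []
    for g, (lo, hi) in enumerate(config.linker_length_ranges):
        linker = [aa[k] for k in rng.integers(len(aa), size=hi)]
        consensus_linkers.append(linker)
    for g, off, letter in config.sbs_plant:
        consensus_linkers[g][off] = letter
    signal = ""
    if config.signal_peptide_length:
        signal = "M" + "".join(
            aa[k] for k in rng.integers(len(aa), size=config.signal_peptide_length - 1)
        )
    tail = "".join(aa[k] for k in rng.integers(len(aa), size=config.c_tail_length))

    # landmark offsets (0-based) within each CSR motif, never mutated
    landmark_offsets: dict[str, set[int]] = {name: set() for name in order}
    for col in (*layout.triad_columns, *layout.chloride_columns):
        landmark_offsets[layout.csr_of(col)].add(layout.offset(col) - 1)

    records: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_sequences):
        lengths = tuple(
            int(rng.integers(lo, hi + 1)) for lo, hi in config.linker_length_ranges
        )
        parts: list[str] = []
        csr_starts: dict[str, int] = {}
        sbs_positions: list[tuple[int, str]] = []
        pos = len(signal)
        fingerprint_parts: list[str] = []
        for k, name in enumerate(order):
            block = list(motifs[name])
            if not config.protect_csr:
                _mutate(block, landmark_offsets[name], config.substitution_rate, rng)
            csr_starts[name] = pos + 1
            pos += len(block)
            parts.append("".join(block))
            fingerprint_parts.append("".join(block))
            if k < len(order) - 1:
                linker = list(consensus_linkers[k][: lengths[k]])
                planted = {
                    off for g, off, _ in config.sbs_plant if g == k and off < lengths[k]
                }
                _mutate(linker, planted, config.substitution_rate, rng)
                for g, off, letter in config.sbs_plant:
                    if g == k and off < lengths[k]:
                        sbs_positions.append((pos + off + 1, letter))
                pos += lengths[k]
                parts.append("".join(linker))
        body = "".join(parts)
        tail_piece = list(tail)
        _mutate(tail_piece, set(), config.substitution_rate, rng)
        residues = signal + body + "".join(tail_piece)

        fingerprint = "".join(fingerprint_parts)
        accession = f"{config.accession_prefix}{i:04d}"
        records.append(
            SequenceRecord(
                accession=accession,
                residues=residues,
                organism=f"Synthetica amylovora {i}",
                subfamily=config.subfamily,
                taxon_domain="unknown",
            )
        )
        c26, c44, c50 = (fingerprint[c - 1] for c in layout.chloride_columns)
        truths.append(
            TruthRecord(
                accession=accession,
                subfamily=config.subfamily,
                fingerprint=fingerprint,
                csr_starts=csr_starts,
                triad_positions=tuple(
                    csr_starts[layout.csr_of(c)] + layout.offset(c) - 1
                    for c in layout.triad_columns
                ),
                chloride_capable=(c26 == "R" and c44 == "N" and c50 in "RK"),
                sbs_positions=tuple(sorted(sbs_positions)),
                linker_lengths=lengths,
                signal_length=len(signal),
                tail_length=len(tail),
            )
        )
    return records, truths


def generate_truth_msa(
    records: list[SequenceRecord],
    truths: list[TruthRecord],
    layout: CsrLayout = DEFAULT_LAYOUT,
) -> Msa:
    """The oracle alignment: pad each linker to its family-wide maximum.

    CSR columns line up exactly across all rows, so slicing the planted
    CSR columns out of this alignment reproduces every truth fingerprint.
    """
    if len(records) != len(truths) or any(
        r.accession != t.accession for r, t in zip(records, truths)
    ):
        raise ValueError("records and truths do not match up")
    order = layout.order
    max_len = [max(t.linker_lengths[g] for t in truths) for g in range(7)]
    max_tail = max(t.tail_length for t in truths)
    rows = []
    for rec, truth in zip(records, truths):
        seq = rec.residues
        out = [seq[: truth.signal_length]]
        pos = truth.signal_length
        for k, name in enumerate(order):
            w = layout.width(name)
            out.append(seq[pos : pos + w])
            pos += w
            if k < len(order) - 1:
                lk = truth.linker_lengths[k]
                out.append(seq[pos : pos + lk] + GAP * (max_len[k] - lk))
                pos += lk
        tail = seq[pos:]
        out.append(tail + GAP * (max_tail - len(tail)))
        rows.append("".join(out))
    return Msa([r.accession for r in records], rows)


def reference_annotation(truth: TruthRecord) -> ReferenceAnnotation:
    """Turn one truth record into a CSR reference annotation."""
    return ReferenceAnnotation(
        accession=truth.accession,
        subfamily=truth.subfamily,
        csr_starts=dict(truth.csr_starts),
        triad_positions=truth.triad_positions,
    )


def truth_fingerprints(truths: list[TruthRecord]) -> list[Fingerprint]:
    return [
        Fingerprint(accession=t.accession, sequence=t.fingerprint, subfamily=t.subfamily)
        for t in truths
    ]


def synthetic_sbs_template(truth: TruthRecord) -> SbsTemplate:
    """Build a synthetic SBS template from one record's planted aromatics.

    The resulting object plays the role of a solved-structure template for
    pipeline runs on generated data; its PDB code is the reserved marker
    ``SYN0``.
    """
    if not truth.sbs_positions:
        raise ValueError(f"record {truth.accession} has no planted SBS residues")
    residues = tuple(
        SbsResidue(letter=letter, mature_pos=pos - truth.signal_length, precursor_pos=pos)
        for pos, letter in truth.sbs_positions
    )
    return SbsTemplate(
        pdb_code="SYN0",
        subfamily=truth.subfamily,
        source_organism="synthetic consensus",
        sites=(SbsSite(name="SBS-I", residues=residues),),
    )


def write_truth_table(truths: list[TruthRecord], path: str | Path) -> None:
    """Tab-separated truth table (one row per generated record)."""
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "accession\tsubfamily\tfingerprint\tchloride_capable\t"
            "triad_positions\tcsr_starts\tsbs_positions\n"
        )
        for t in truths:
            starts = ",".join(f"{k}:{v}" for k, v in t.csr_starts.items())
            sbs = ",".join(f"{p}{letter}" for p, letter in t.sbs_positions)
            fh.write(
                f"{t.accession}\t{t.subfamily}\t{t.fingerprint}\t"
                f"{int(t.chloride_capable)}\t"
                f"{','.join(map(str, t.triad_positions))}\t{starts}\t{sbs}\n"
            )
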