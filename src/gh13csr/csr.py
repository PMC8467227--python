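"""The 55-column CSR coordinate system: anchoring, trimming, extraction.

Family GH13 alpha-amylases share eight conserved sequence regions (CSRs)
spread over the catalytic TIM-barrel.  Concatenated in their order along
the chain (CSR-VIII, VI, I, V, II, III, IV, VII) they form a 55-position
"fingerprint" whose landmark columns carry the catalytic triad
(Asp28 nucleophile, Glu37 proton donor, Asp46 transition-state
stabilizer) and the chloride-binding triad sites (26, 44, 50).

Anchoring is reference-guided: one alignment row with known CSR start
positions pins every fingerprint column to an alignment column, which
replaces the manual alignment curation a human expert would perform.
A conservation-driven fallback (:func:`infer_reference_by_conservation`)
is available when no annotated row exists; it is a documented heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .registry import CSR_SEQUENCE_ORDER, ReferenceAnnotation
from .seqio import GAP, Msa


@dataclass(frozen=True)
class CsrSpan:
    name: str
    start: int  # 1-based fingerprint column of the first residue
    end: int    # inclusive

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CsrLayout:
    """Partition of fingerprint columns 1..55 into the eight CSRs."""

    spans: tuple[CsrSpan, ...]
    nucleophile: int = 28
    proton_donor: int = 37
    stabilizer: int = 46
    chloride_arg: int = 26
    chloride_asn: int = 44
    chloride_arg_lys: int = 50

    def __post_init__(self) -> None:
        expected = 1
        for span in self.spans:
            if span.start != expected:
                raise ValueError(
                    f"layout spans must be contiguous from column 1; "
                    f"{span.name} starts at {span.start}, expected {expected}"
                )
            expected = span.end + 1
        if tuple(s.name for s in self.spans) != CSR_SEQUENCE_ORDER:
            raise ValueError("layout spans must follow the chain order of the CSRs")
        for pos, csr in [
            (self.nucleophile, "CSR-II"),
            (self.proton_donor, "CSR-III"),
            (self.stabilizer, "CSR-IV"),
            (self.chloride_arg, "CSR-II"),
            (self.chloride_asn, "CSR-IV"),
            (self.chloride_arg_lys, "CSR-VII"),
        ]:
            if self.csr_of(pos) != csr:
                raise ValueError(f"landmark column {pos} must fall inside {csr}")

    @property
    def total_width(self) -> int:
        return self.spans[-1].end

    @property
    def order(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.spans)

    def span(self, name: str) -> CsrSpan:
        for s in self.spans:
            if s.name == name:
                return s
        raise KeyError(f"unknown CSR {name!r}")

    def width(self, name: str) -> int:
        return self.span(name).width

    def csr_of(self, column: int) -> str:
        """Name of the CSR containing a 1-based fingerprint column."""
        for s in self.spans:
            if s.start <= column <= s.end:
                return s.name
        raise IndexError(f"fingerprint column {column} outside 1..{self.total_width}")

    def offset(self, column: int) -> int:
        """1-based offset of a fingerprint column within its CSR."""
        s = self.span(self.csr_of(column))
        return column - s.start + 1

    @property
    def triad_columns(self) -> tuple[int, int, int]:
        return (self.nucleophile, self.proton_donor, self.stabilizer)

    @property
    def chloride_columns(self) -> tuple[int, int, int]:
        return (self.chloride_arg, self.chloride_asn, self.chloride_arg_lys)


DEFAULT_LAYOUT = CsrLayout(
    spans=(
        CsrSpan("CSR-VIII", 1, 3),
        CsrSpan("CSR-VI", 4, 12),
        CsrSpan("CSR-I", 13, 18),
        CsrSpan("CSR-V", 19, 23),
        CsrSpan("CSR-II", 24, 32),
        CsrSpan("CSR-III", 33, 40),
        CsrSpan("CSR-IV", 41, 46),
        CsrSpan("CSR-VII", 47, 55),
    )
)


@dataclass(frozen=True)
class AnchorSet:
    """Alignment columns of every fingerprint position, via a reference row.

    ``csr_columns`` maps each CSR name to the (1-based) alignment columns
    of the reference residues of that CSR, in order.  ``beta1_start`` and
    ``beta8_end`` delimit the barrel segment used for trimming.
    """

    reference: str
    csr_columns: dict[str, tuple[int, ...]]
    triad_columns: tuple[int, int, int]
    beta1_start: int
    beta8_end: int

    def fingerprint_columns(self, layout: CsrLayout = DEFAULT_LAYOUT) -> tuple[int, ...]:
        cols: list[int] = []
        for name in layout.order:
            cols.extend(self.csr_columns[name])
        return tuple(cols)


@dataclass(frozen=True)
class Fingerprint:
    """A 55-character CSR extract for one sequence ('-' where gapped)."""

    accession: str
    sequence: str
    subfamily: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.sequence) != DEFAULT_LAYOUT.total_width:
            raise ValueError(
                f"fingerprint {self.accession}: length {len(self.sequence)}, "
                f"expected {DEFAULT_LAYOUT.total_width}"
            )

    def at(self, column: int) -> str:
        """Residue at a 1-based fingerprint column."""
        return self.sequence[column - 1]


def _column_map(row: str) -> list[int]:
    """1-based alignment column of each ungapped residue of ``row``."""
    return [j + 1 for j, ch in enumerate(row) if ch != GAP]


def locate_anchors(
    msa: Msa,
    reference: ReferenceAnnotation,
    layout: CsrLayout = DEFAULT_LAYOUT,
) -> AnchorSet:
    """Pin each CSR of the layout to alignment columns via the reference row.

    The reference row must carry Asp/Glu/Asp at its annotated catalytic
    triad positions and must be gap-free inside every CSR span.
    """
    reference.validate_against_layout(layout)
    row = msa.row(reference.accession)
    colmap = _column_map(row)
    n_res = len(colmap)

    def col(pos: int) -> int:
        if not 1 <= pos <= n_res:
            raise ValueError(
                f"reference {reference.accession}: position {pos} outside "
                f"ungapped length {n_res}"
            )
        return colmap[pos - 1]

    triad_letters = "".join(row[col(p) - 1] for p in reference.triad_positions)
    if triad_letters != "DED":
        raise ValueError(
            f"catalytic triad mismatch: reference {reference.accession} shows "
            f"{'/'.join(triad_letters)} at positions {reference.triad_positions}, "
            "expected D/E/D"
        )

    csr_columns: dict[str, tuple[int, ...]] = {}
    for name in layout.order:
        start = reference.csr_starts[name]
        width = layout.width(name)
        cols = tuple(col(start + k) for k in range(width))
        # CSRs are gapless blocks; insertions against the reference inside
        # a CSR would break the fixed layout widths, so they are rejected.
        for c in range(cols[0], cols[-1] + 1):
            if row[c - 1] == GAP:
                raise ValueError(
                    f"reference {reference.accession} has a gap inside {name} "
                    f"(alignment column {c})"
                )
        csr_columns[name] = cols

    return AnchorSet(
        reference=reference.accession,
        csr_columns=csr_columns,
        triad_columns=tuple(col(p) for p in reference.triad_positions),
        beta1_start=csr_columns[layout.order[0]][0],
        beta8_end=csr_columns[layout.order[-1]][-1],
    )


def trim_beta_segment(msa: Msa, anchors: AnchorSet) -> Msa:
    """Drop alignment columns outside the beta1..beta8 barrel segment."""
    return msa.select_columns(range(anchors.beta1_start, anchors.beta8_end + 1))


def extract_fingerprints(
    msa: Msa,
    anchors: AnchorSet,
    layout: CsrLayout = DEFAULT_LAYOUT,
    subfamilies: dict[str, str] | None = None,
) -> list[Fingerprint]:
    """Read the 55 fingerprint columns off every alignment row.

    Rows gapped at an anchored column carry ``'-'`` at that fingerprint
    position.
    """
    for name in layout.order:
        if len(anchors.csr_columns.get(name, ())) != layout.width(name):
            raise ValueError(
                f"anchor span for {name} has {len(anchors.csr_columns.get(name, ()))} "
                f"columns, layout requires {layout.width(name)}"
            )
    cols = anchors.fingerprint_columns(layout)
    out = []
    for rid, row in zip(msa.row_ids, msa.rows):
        seq = "".join(row[c - 1] for c in cols)
        sub = subfamilies.get(rid, "unknown") if subfamilies else "unknown"
        out.append(Fingerprint(accession=rid, sequence=seq, subfamily=sub))
    return out


def infer_reference_by_conservation(
    msa: Msa,
    layout: CsrLayout = DEFAULT_LAYOUT,
    min_spacing: int = 4,
) -> ReferenceAnnotation:
    """Heuristic fallback: derive a reference annotation with no prior labels.

    Scans for the alignment-column triple most conserved for Asp/Glu/Asp
    with chain-compatible spacing, picks the row matching that pattern
    with the fewest gaps, and places the remaining CSR windows on that
    row at layout-compatible offsets maximizing column conservation.
    Intended for exploration only; an annotated reference is always
    preferred.
    """
    if not msa.rows:
        raise ValueError("empty alignment")
    width = msa.width
    n = len(msa)
    frac = {
        aa: [msa.column(j).count(aa) / n for j in range(1, width + 1)]
        for aa in "DERN"
    }
    conserved = [
        (max(msa.column(j).count(aa) for aa in set(msa.column(j)) - {GAP} or {"-"}) / n)
        for j in range(1, width + 1)
    ]

    def block_mean(lo: int, hi: int) -> float:
        lo, hi = max(lo, 1), min(hi, width)
        return sum(conserved[j - 1] for j in range(lo, hi + 1)) / (hi - lo + 1)

    best, best_score = None, -1.0
    d_cols = [j for j in range(1, width + 1) if frac["D"][j - 1] > 0.5]
    e_cols = [j for j in range(1, width + 1) if frac["E"][j - 1] > 0.5]
    # two family-invariant context signals sharpen the search: the Arg two
    # columns before the nucleophile, the Asn two before the stabilizer,
    # and the conservation of the whole CSR window each candidate implies
    for c1 in d_cols:
        ctx1 = frac["R"][c1 - 3] if c1 > 2 else 0.0
        w1 = block_mean(c1 - (layout.nucleophile - layout.span("CSR-II").start),
                        c1 + (layout.span("CSR-II").end - layout.nucleophile))
        for c2 in e_cols:
            if c2 < c1 + min_spacing:
                continue
            w2 = block_mean(c2 - (layout.proton_donor - layout.span("CSR-III").start),
                            c2 + (layout.span("CSR-III").end - layout.proton_donor))
            for c3 in d_cols:
                if c3 < c2 + min_spacing:
                    continue
                ctx3 = frac["N"][c3 - 3] if c3 > 2 else 0.0
                w3 = block_mean(c3 - (layout.stabilizer - layout.span("CSR-IV").start),
                                c3 + (layout.span("CSR-IV").end - layout.stabilizer))
                score = (
                    frac["D"][c1 - 1]
                    * frac["E"][c2 - 1]
                    * frac["D"][c3 - 1]
                    * (0.5 + ctx1)
                    * (0.5 + ctx3)
                    * w1 * w2 * w3
                )
                if score > best_score:
                    best, best_score = (c1, c2, c3), score
    if best is None:
        raise ValueError("no conserved D/E/D column triple found")
    c_nuc, c_don, c_stab = best

    # choose the reference row: D/E/D at the triple, fewest gaps overall
    candidates = [
        (row.count(GAP), i)
        for i, row in enumerate(msa.rows)
        if row[c_nuc - 1] == "D" and row[c_don - 1] == "E" and row[c_stab - 1] == "D"
    ]
    if not candidates:
        raise ValueError("no row carries D/E/D at the conserved triple")
    _, ref_idx = min(candidates)
    rid, row = msa.row_ids[ref_idx], msa.rows[ref_idx]
    colmap = _column_map(row)
    pos_of_col = {c: p + 1 for p, c in enumerate(colmap)}

    nuc_pos = pos_of_col[c_nuc]
    don_pos = pos_of_col[c_don]
    stab_pos = pos_of_col[c_stab]
    starts = {
        "CSR-II": nuc_pos - (layout.nucleophile - layout.span("CSR-II").start),
        "CSR-III": don_pos - (layout.proton_donor - layout.span("CSR-III").start),
        "CSR-IV": stab_pos - (layout.stabilizer - layout.span("CSR-IV").start),
    }

    conservation = conserved

    def window_score(start_pos: int, w: int) -> float:
        cols = colmap[start_pos - 1 : start_pos - 1 + w]
        mean = sum(conservation[c - 1] for c in cols) / w
        # a CSR occupies a gapless block of columns; windows straddling
        # insert columns are down-weighted so they only win over real gaps
        # in conservation
        if cols[-1] - cols[0] + 1 != w:
            mean *= 0.98
        return mean

    # place remaining CSRs greedily in chain order within free intervals
    order = list(layout.order)
    bounds: dict[str, int] = dict(starts)
    n_res = len(colmap)
    for idx, name in enumerate(order):
        if name in bounds:
            continue
        w = layout.width(name)
        prev_end = 1
        for before in reversed(order[:idx]):
            if before in bounds:
                prev_end = bounds[before] + layout.width(before)
                break
        next_start = n_res - w + 1
        for j_after, after in enumerate(order[idx + 1 :], start=idx + 1):
            if after in bounds:
                # leave room for every unplaced CSR between here and `after`
                reserved = sum(layout.width(x) for x in order[idx:j_after])
                next_start = bounds[after] - reserved
                break
        lo, hi = prev_end, max(prev_end, next_start)
        best_start, best_ws = lo, -1.0
        for s in range(lo, hi + 1):
            if s + w - 1 > n_res:
                break
            ws = window_score(s, w)
            if ws > best_ws:
                best_start, best_ws = s, ws
        bounds[name] = best_start
    return ReferenceAnnotation(
        accession=rid,
        subfamily="unknown",
        csr_starts=bounds,
        triad_positions=(nuc_pos, don_pos, stab_pos),
    )
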