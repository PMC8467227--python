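"""Chloride-binding capability calls from CSR fingerprints.

Chloride-activated alpha-amylases coordinate the anion with an
arginine, an asparagine and a second arginine that may be replaced by
a lysine.  On the 55-column fingerprint these sites are columns 26
(CSR-II, two before the catalytic nucleophile), 44 (CSR-IV) and 50
(CSR-VII).  A sequence is called capable exactly when it shows R, N
and R-or-K there; any other letter, an ``X`` or a gap marks that site
as missing.  Only those three columns matter — the remaining 52 are
ignored by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .csr import DEFAULT_LAYOUT, CsrLayout, Fingerprint

_SITE_NAMES = ("arg26", "asn44", "arg_lys50")


@dataclass(frozen=True)
class ChlorideVerdict:
    accession: str
    site26: str
    site44: str
    site50: str
    capable: bool
    variant: str  # arg | lys | none
    missing_sites: tuple[str, ...]
    subfamily: str = "unknown"


def classify(
    fingerprint: Fingerprint | str, layout: CsrLayout = DEFAULT_LAYOUT
) -> ChlorideVerdict:
    """Verdict for one fingerprint under the R26/N44/R-K50 triad rule."""
    if isinstance(fingerprint, Fingerprint):
        seq = fingerprint.sequence
        accession = fingerprint.accession
        subfamily = fingerprint.subfamily
    else:
        seq = str(fingerprint)
        accession = "?"
        subfamily = "unknown"
    if len(seq) != layout.total_width:
        raise ValueError(
            f"fingerprint {accession}: length {len(seq)}, expected {layout.total_width}"
        )
    c26, c44, c50 = (seq[c - 1] for c in layout.chloride_columns)
    missing = []
    if c26 != "R":
        missing.append(_SITE_NAMES[0])
    if c44 != "N":
        missing.append(_SITE_NAMES[1])
    if c50 not in ("R", "K"):
        missing.append(_SITE_NAMES[2])
    capable = not missing
    if capable:
        variant = "lys" if c50 == "K" else "arg"
    else:
        variant = "none"
    return ChlorideVerdict(
        accession=accession,
        site26=c26,
        site44=c44,
        site50=c50,
        capable=capable,
        variant=variant,
        missing_sites=tuple(missing),
        subfamily=subfamily,
    )


def classify_all(
    fingerprints: list[Fingerprint], layout: CsrLayout = DEFAULT_LAYOUT
) -> list[ChlorideVerdict]:
    return [classify(fp, layout) for fp in fingerprints]


def summarize(verdicts: list[ChlorideVerdict]) -> pd.DataFrame:
    """Per-subfamily counts of capable, lysine-variant and missing-site calls."""
    rows = []
    groups: dict[str, list[ChlorideVerdict]] = {}
    for v in verdicts:
        groups.setdefault(v.subfamily, []).append(v)
    for subfamily in sorted(groups):
        vs = groups[subfamily]
        rows.append(
            {
                "subfamily": subfamily,
                "n": len(vs),
                "capable": sum(v.capable for v in vs),
                "lys_variant": sum(v.variant == "lys" for v in vs),
                "missing_arg26": sum(_SITE_NAMES[0] in v.missing_sites for v in vs),
                "missing_asn44": sum(_SITE_NAMES[1] in v.missing_sites for v in vs),
                "missing_arg_lys50": sum(
                    _SITE_NAMES[2] in v.missing_sites for v in vs
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subfamily",
            "n",
            "capable",
            "lys_variant",
            "missing_arg26",
            "missing_asn44",
            "missing_arg_lys50",
        ],
    )


def write_verdict_table(verdicts: list[ChlorideVerdict], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "accession\tsubfamily\tsite26\tsite44\tsite50\tcapable\tvariant\t"
            "missing_sites\n"
        )
        for v in verdicts:
            fh.write(
                f"{v.accession}\t{v.subfamily}\t{v.site26}\t{v.site44}\t{v.site50}\t"
                f"{int(v.capable)}\t{v.variant}\t{','.join(v.missing_sites)}\n"
            )
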