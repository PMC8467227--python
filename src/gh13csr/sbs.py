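"""Surface-binding-site (SBS) correspondence mapping and conservation.

An SBS is a ligand-binding patch on the enzyme surface, outside the
active site, typically built from aromatic residues (F/W/Y).  SBSs are
known only from solved complex structures; to ask whether homologues
may share one, each template residue is mapped through the alignment
row of the template sequence onto an alignment column, the residue at
that column is read off for every other sequence, and conservation of
the aromatic character is tallied.

Published correspondence grids for the three subfamilies with solved
SBS templates ship with the package as plain TSV files and can be fed
straight into :func:`conservation_summary` without any sequence
download.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .registry import AROMATIC, SbsTemplate, _data_path, get_template
from .seqio import GAP, Msa

_GRID_FILES = {
    "GH13_1": "sbs_grid_gh13_1.tsv",
    "GH13_5": "sbs_grid_gh13_5.tsv",
    "GH13_24": "sbs_grid_gh13_24.tsv",
}


@dataclass(frozen=True)
class MappedResidue:
    site_name: str
    letter: str
    position: int  # in the chosen numbering of the template sequence
    column: int    # 1-based alignment column


@dataclass(frozen=True)
class SbsObservation:
    site_name: str
    template_letter: str
    template_position: int
    observed: str
    aromatic: bool


@dataclass(frozen=True)
class SbsCorrespondence:
    accession: str
    pdb_code: str
    observations: tuple[SbsObservation, ...]


def map_template_columns(
    template: SbsTemplate,
    msa: Msa,
    template_row: str,
    numbering: str = "mature",
) -> list[MappedResidue]:
    """Alignment columns of every template SBS residue.

    ``numbering`` selects mature (signal peptide removed) or precursor
    residue numbers; the letter found on the template row at each mapped
    column must equal the template letter, otherwise the numbering mode
    or the row is wrong and an error is raised.
    """
    row = msa.row(template_row)
    colmap = [j + 1 for j, ch in enumerate(row) if ch != GAP]
    mapped = []
    for site_name, res in template.iter_residues():
        pos = res.position(numbering)
        if not 1 <= pos <= len(colmap):
            raise ValueError(
                f"template {template.pdb_code} {site_name} {res.letter}{pos}: "
                f"position exceeds ungapped length {len(colmap)} of row "
                f"{template_row!r}"
            )
        column = colmap[pos - 1]
        found = row[column - 1]
        if found != res.letter:
            raise ValueError(
                f"template residue mismatch: {template.pdb_code} {site_name} "
                f"expects {res.letter}{pos} ({numbering} numbering) but row "
                f"{template_row!r} shows {found!r} at alignment column {column}"
            )
        mapped.append(
            MappedResidue(
                site_name=site_name, letter=res.letter, position=pos, column=column
            )
        )
    return mapped


def correspondences(
    template: SbsTemplate, mapping: list[MappedResidue], msa: Msa
) -> list[SbsCorrespondence]:
    """Observed letters at the mapped columns, one entry per alignment row."""
    out = []
    for rid, row in zip(msa.row_ids, msa.rows):
        obs = tuple(
            SbsObservation(
                site_name=m.site_name,
                template_letter=m.letter,
                template_position=m.position,
                observed=row[m.column - 1],
                aromatic=row[m.column - 1] in AROMATIC,
            )
            for m in mapping
        )
        out.append(
            SbsCorrespondence(accession=rid, pdb_code=template.pdb_code, observations=obs)
        )
    return out


def conservation_summary(corrs: list[SbsCorrespondence]) -> pd.DataFrame:
    """Letter tallies and aromatic fraction per template residue.

    One output row per (template, site, residue); the ``counts`` column
    holds a ``letter=count`` breakdown sorted by decreasing count.
    """
    buckets: dict[tuple[str, str, str, int], dict[str, int]] = {}
    order: list[tuple[str, str, str, int]] = []
    for corr in corrs:
        for ob in corr.observations:
            key = (corr.pdb_code, ob.site_name, ob.template_letter, ob.template_position)
            if key not in buckets:
                buckets[key] = {}
                order.append(key)
            buckets[key][ob.observed] = buckets[key].get(ob.observed, 0) + 1
    rows = []
    for key in order:
        counts = buckets[key]
        n = sum(counts.values())
        aromatic = sum(c for letter, c in counts.items() if letter in AROMATIC)
        breakdown = ";".join(
            f"{letter}={c}"
            for letter, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        )
        rows.append(
            {
                "pdb_code": key[0],
                "site": key[1],
                "template_residue": f"{key[2]}{key[3]}",
                "n": n,
                "aromatic": aromatic,
                "aromatic_fraction": aromatic / n if n else 0.0,
                "counts": breakdown,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pdb_code",
            "site",
            "template_residue",
            "n",
            "aromatic",
            "aromatic_fraction",
            "counts",
        ],
    )


def load_packaged_grid(subfamily: str) -> list[SbsCorrespondence]:
    """Published correspondence grid for a subfamily with solved templates.

    Returns one :class:`SbsCorrespondence` per record and template; grids
    exist for GH13_1, GH13_5 and GH13_24.
    """
    if subfamily not in _GRID_FILES:
        raise KeyError(
            f"no packaged SBS grid for {subfamily!r}; available: "
            + ", ".join(sorted(_GRID_FILES))
        )
    path = _data_path(_GRID_FILES[subfamily])
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        columns = []
        for token in header[1:]:
            pdb, site, respec = token.split(":")
            columns.append((pdb, site, respec[0], int(respec[1:])))
        per_record: list[tuple[str, list[str]]] = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(f"malformed grid row in {path}: {line!r}")
            per_record.append((fields[0], fields[1:]))
    out = []
    for record_id, letters in per_record:
        by_pdb: dict[str, list[SbsObservation]] = {}
        for (pdb, site, letter, pos), observed in zip(columns, letters):
            by_pdb.setdefault(pdb, []).append(
                SbsObservation(
                    site_name=site,
                    template_letter=letter,
                    template_position=pos,
                    observed=observed,
                    aromatic=observed in AROMATIC,
                )
            )
        for pdb, obs in by_pdb.items():
            # sanity: the grid's template columns must exist in the registry
            get_template(pdb)
            out.append(
                SbsCorrespondence(
                    accession=record_id, pdb_code=pdb, observations=tuple(obs)
                )
            )
    return out


def write_correspondence_table(
    corrs: list[SbsCorrespondence], path: str | Path
) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "accession\tpdb_code\tsite\ttemplate_residue\tobserved\taromatic\n"
        )
        for corr in corrs:
            for ob in corr.observations:
                fh.write(
                    f"{corr.accession}\t{corr.pdb_code}\t{ob.site_name}\t"
                    f"{ob.template_letter}{ob.template_position}\t{ob.observed}\t"
                    f"{int(ob.aromatic)}\n"
                )
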