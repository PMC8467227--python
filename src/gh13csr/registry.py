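"""Packaged fixed knowledge: study-set manifest, SBS templates, references.

The data live in ``data/registry.yaml`` inside the package and are
validated on load.  Nothing here touches the network; the manifest
records how many sequences of each GH13 subfamily (split into
prokaryotic and eukaryotic origin) the analysed study set contains,
and the templates describe the solved structures whose experimentally
identified surface-binding sites (SBSs) drive the correspondence
mapping in :mod:`gh13csr.sbs`.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .seqio import SUBFAMILIES

AROMATIC = frozenset("FWY")

#: Sequential order of the eight CSRs along the polypeptide chain
#: (beta-strand order of the TIM-barrel: beta1 carries CSR-VIII, beta2
#: CSR-VI, beta3 CSR-I, the domain-B strand CSR-V, beta4 CSR-II, beta5
#: CSR-III, beta7 CSR-IV and beta8 CSR-VII).
CSR_SEQUENCE_ORDER = (
    "CSR-VIII",
    "CSR-VI",
    "CSR-I",
    "CSR-V",
    "CSR-II",
    "CSR-III",
    "CSR-IV",
    "CSR-VII",
)


@dataclass(frozen=True)
class Manifest:
    """Per-subfamily (procarya, eucarya) sequence counts of the study set."""

    counts: dict[str, tuple[int, int]]

    def total(self, subfamily: str) -> int:
        p, e = self.counts[subfamily]
        return p + e

    @property
    def grand_total(self) -> int:
        return sum(p + e for p, e in self.counts.values())


@dataclass(frozen=True)
class SbsResidue:
    letter: str
    mature_pos: int
    precursor_pos: int

    def position(self, numbering: str) -> int:
        if numbering == "mature":
            return self.mature_pos
        if numbering == "precursor":
            return self.precursor_pos
        raise ValueError(f"unknown numbering {numbering!r} (use mature|precursor)")


@dataclass(frozen=True)
class SbsSite:
    name: str
    residues: tuple[SbsResidue, ...]


@dataclass(frozen=True)
class SbsTemplate:
    """One solved structure with its named surface-binding sites."""

    pdb_code: str
    subfamily: str
    source_organism: str
    sites: tuple[SbsSite, ...]
    aliases: tuple[str, ...] = ()
    variant_note: str = ""

    def __post_init__(self) -> None:
        if len(self.pdb_code) != 4:
            raise ValueError(f"PDB code must have 4 characters: {self.pdb_code!r}")
        if not self.sites:
            raise ValueError(f"template {self.pdb_code}: needs at least one site")
        for site in self.sites:
            for res in site.residues:
                if res.letter not in AROMATIC:
                    raise ValueError(
                        f"template {self.pdb_code} {site.name}: residue letter "
                        f"{res.letter!r} is not aromatic (F/W/Y)"
                    )
                if res.mature_pos > res.precursor_pos:
                    raise ValueError(
                        f"template {self.pdb_code} {site.name}: mature position "
                        f"{res.mature_pos} exceeds precursor {res.precursor_pos}"
                    )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def iter_residues(self):
        """Yield ``(site_name, SbsResidue)`` in registry order."""
        for site in self.sites:
            for res in site.residues:
                yield site.name, res


@dataclass(frozen=True)
class ReferenceAnnotation:
    """CSR starts and catalytic-triad positions on one ungapped sequence.

    Positions are 1-based indices into the ungapped residues.  The triad
    is the catalytic nucleophile (Asp, CSR-II), proton donor (Glu,
    CSR-III) and transition-state stabilizer (Asp, CSR-IV).
    """

    accession: str
    subfamily: str
    csr_starts: dict[str, int]
    triad_positions: tuple[int, int, int]

    def __post_init__(self) -> None:
        missing = set(CSR_SEQUENCE_ORDER) - set(self.csr_starts)
        if missing:
            raise ValueError(f"reference {self.accession}: missing CSR starts {sorted(missing)}")
        starts = [self.csr_starts[name] for name in CSR_SEQUENCE_ORDER]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError(
                f"reference {self.accession}: CSR starts must increase in the "
                f"order {' < '.join(CSR_SEQUENCE_ORDER)}"
            )

    def validate_against_layout(self, layout) -> None:
        """Check triad positions fall inside CSR-II/III/IV given a layout."""
        for pos, csr in zip(self.triad_positions, ("CSR-II", "CSR-III", "CSR-IV")):
            start = self.csr_starts[csr]
            width = layout.width(csr)
            if not start <= pos < start + width:
                raise ValueError(
                    f"reference {self.accession}: triad position {pos} outside {csr}"
                )


def _data_path(name: str) -> Path:
    return Path(resources.files("gh13csr").joinpath("data", name))


@functools.lru_cache(maxsize=1)
def _load_registry() -> dict:
    with open(_data_path("registry.yaml")) as fh:
        return yaml.safe_load(fh)


def load_manifest() -> Manifest:
    """The study-set manifest: six subfamilies, 268 sequences in total."""
    raw = _load_registry()["manifest"]
    counts = {}
    for sub in SUBFAMILIES:
        entry = raw[sub]
        p, e = int(entry["procarya"]), int(entry["eucarya"])
        if p < 0 or e < 0:
            raise ValueError(f"manifest {sub}: negative count")
        counts[sub] = (p, e)
    return Manifest(counts=counts)


def _parse_template(raw: dict) -> SbsTemplate:
    sites = tuple(
        SbsSite(
            name=s["name"],
            residues=tuple(
                SbsResidue(r["letter"], int(r["mature"]), int(r["precursor"]))
                for r in s["residues"]
            ),
        )
        for s in raw["sites"]
    )
    return SbsTemplate(
        pdb_code=raw["pdb_code"],
        subfamily=raw["subfamily"],
        source_organism=raw["source_organism"],
        sites=sites,
        aliases=tuple(raw.get("aliases", ())),
        variant_note=raw.get("variant_note", ""),
    )


@functools.lru_cache(maxsize=1)
def _templates() -> dict[str, SbsTemplate]:
    out: dict[str, SbsTemplate] = {}
    for raw in _load_registry()["templates"]:
        tpl = _parse_template(raw)
        out[tpl.pdb_code] = tpl
        for alias in tpl.aliases:
            out[alias] = tpl
    return out


def list_templates() -> list[str]:
    """Registered PDB codes, aliases included, sorted."""
    return sorted(_templates())


def get_template(pdb_code: str) -> SbsTemplate:
    """Look up an SBS template by PDB code (aliases accepted)."""
    templates = _templates()
    code = pdb_code.upper()
    if code not in templates:
        raise KeyError(
            f"unknown template {pdb_code!r}; registered codes: "
            + ", ".join(list_templates())
        )
    return templates[code]


def chloride_reference() -> dict:
    """Documentation of the chloride-triad numbering in the reference enzyme."""
    return dict(_load_registry()["chloride_reference"])


def load_reference_annotation(path: str | Path) -> ReferenceAnnotation:
    """Read a user-supplied reference annotation from a small YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ReferenceAnnotation(
        accession=raw["accession"],
        subfamily=raw.get("subfamily", "unknown"),
        csr_starts={str(k): int(v) for k, v in raw["csr_starts"].items()},
        triad_positions=tuple(int(v) for v in raw["triad_positions"]),
    )


def save_reference_annotation(annotation: ReferenceAnnotation, path: str | Path) -> None:
    payload = {
        "accession": annotation.accession,
        "subfamily": annotation.subfamily,
        "csr_starts": dict(annotation.csr_starts),
        "triad_positions": list(annotation.triad_positions),
    }
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
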