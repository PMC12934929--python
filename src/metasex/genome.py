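"""Host genome description: chromosome inventory, sex system, copy numbers.

Sex inference from read counts needs to know, for every reference sequence,
its length, whether it is an autosome or a sex chromosome, and how many
copies each sex carries.  In an XY system females are XX (homogametic) and
males XY (heterogametic); in a ZW system the roles flip: males are ZZ and
females ZW.  A :class:`GenomeSpec` is the single source of truth for which
counts feed the coverage statistics downstream.

Exclusion regions (pseudoautosomal regions and other shared sequence) are
handled as *effective length* adjustments: counts are produced upstream of
this package, so masking a region only changes the denominator of the
coverage calculation, never the counts themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import yaml

__all__ = [
    "Role",
    "SexSystem",
    "SexClass",
    "ChromRecord",
    "GenomeSpec",
    "GenomeSpecError",
    "DuplicateChromosomeError",
    "MissingSexChromosomeError",
    "InvalidLengthError",
    "ExclusionRegionError",
    "load_genome_spec",
    "save_genome_spec",
    "spec_from_scaffolds",
    "apply_exclusion_regions",
    "read_bed",
    "read_scaffold_list",
    "bundled_spec",
    "sex_label",
    "sex_class_of_label",
]


class Role(str, Enum):
    """Role a reference sequence plays in the coverage model."""

    AUTOSOME = "autosome"
    SEX_HOMOGAMETIC = "sex_homogametic"
    SEX_HETEROGAMETIC = "sex_heterogametic"
    IGNORED = "ignored"


class SexSystem(str, Enum):
    XY = "XY"
    ZW = "ZW"


class SexClass(str, Enum):
    """Karyotype class, independent of the phenotypic label.

    HOMOGAMETIC individuals carry two copies of the homogametic chromosome
    (XX females, ZZ males); HETEROGAMETIC individuals carry one copy of each
    sex chromosome (XY males, ZW females).
    """

    HOMOGAMETIC = "homogametic"
    HETEROGAMETIC = "heterogametic"


class GenomeSpecError(ValueError):
    """Base class for genome specification validation errors."""


class DuplicateChromosomeError(GenomeSpecError):
    pass


class MissingSexChromosomeError(GenomeSpecError):
    pass


class InvalidLengthError(GenomeSpecError):
    pass


class ExclusionRegionError(GenomeSpecError):
    pass


def sex_label(system: SexSystem, sex_class: SexClass) -> str:
    """Phenotypic label ("female"/"male") for a karyotype class under a system."""
    system = SexSystem(system)
    if system is SexSystem.XY:
        return "female" if sex_class is SexClass.HOMOGAMETIC else "male"
    return "male" if sex_class is SexClass.HOMOGAMETIC else "female"


def sex_class_of_label(system: SexSystem, label: str) -> SexClass:
    """Inverse of :func:`sex_label`."""
    for cls in SexClass:
        if sex_label(system, cls) == label:
            return cls
    raise ValueError(f"unknown sex label {label!r}")


@dataclass(frozen=True)
class ChromRecord:
    """One reference sequence with its coverage-model role.

    ``effective_length`` is the number of bases that contribute to coverage
    (length minus excluded spans); it defaults to ``length``.  ``excluded``
    stores the merged half-open exclusion intervals already applied, which
    makes repeated application of the same region set idempotent.
    """

    id: str
    length: int
    role: Role = Role.AUTOSOME
    effective_length: int | None = None
    excluded: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.id:
            raise GenomeSpecError("chromosome id must be non-empty")
        if int(self.length) <= 0:
            raise InvalidLengthError(
                f"chromosome {self.id!r}: length must be positive, got {self.length}"
            )
        object.__setattr__(self, "length", int(self.length))
        object.__setattr__(self, "role", Role(self.role))
        eff = self.length if self.effective_length is None else int(self.effective_length)
        if not (1 <= eff <= self.length):
            raise InvalidLengthError(
                f"chromosome {self.id!r}: effective_length {eff} outside [1, {self.length}]"
            )
        object.__setattr__(self, "effective_length", eff)


@dataclass(frozen=True)
class GenomeSpec:
    """Validated chromosome inventory for one sex-determination system."""

    system: SexSystem
    chromosomes: tuple[ChromRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "system", SexSystem(self.system))
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        seen: set[str] = set()
        for rec in self.chromosomes:
            if rec.id in seen:
                raise DuplicateChromosomeError(f"duplicate chromosome id {rec.id!r}")
            seen.add(rec.id)
        homo = [c for c in self.chromosomes if c.role is Role.SEX_HOMOGAMETIC]
        het = [c for c in self.chromosomes if c.role is Role.SEX_HETEROGAMETIC]
        if len(homo) != 1 or len(het) != 1:
            raise MissingSexChromosomeError(
                "spec must designate exactly one homogametic and one heterogametic "
                f"sex chromosome (got {len(homo)} and {len(het)})"
            )
        if self.n_autosomes < 1:
            raise GenomeSpecError("spec must contain at least one autosome")

    @property
    def autosomes(self) -> tuple[ChromRecord, ...]:
        return tuple(c for c in self.chromosomes if c.role is Role.AUTOSOME)

    @property
    def n_autosomes(self) -> int:
        return len(self.autosomes)

    @property
    def homogametic(self) -> ChromRecord:
        return next(c for c in self.chromosomes if c.role is Role.SEX_HOMOGAMETIC)

    @property
    def heterogametic(self) -> ChromRecord:
        return next(c for c in self.chromosomes if c.role is Role.SEX_HETEROGAMETIC)

    def record(self, chrom_id: str) -> ChromRecord:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(chrom_id)

    def copy_number(self, rec: ChromRecord, sex: SexClass) -> int:
        """Copies of ``rec`` carried by an individual of karyotype class ``sex``."""
        sex = SexClass(sex)
        if rec.role is Role.AUTOSOME:
            return 2
        if rec.role is Role.SEX_HOMOGAMETIC:
            return 2 if sex is SexClass.HOMOGAMETIC else 1
        if rec.role is Role.SEX_HETEROGAMETIC:
            return 0 if sex is SexClass.HOMOGAMETIC else 1
        return 0

    def to_dict(self) -> dict:
        out: dict = {"system": self.system.value, "chromosomes": []}
        for c in self.chromosomes:
            d: dict = {"id": c.id, "length": c.length, "role": c.role.value}
            if c.effective_length != c.length:
                d["effective_length"] = c.effective_length
            if c.excluded:
                d["excluded"] = [list(iv) for iv in c.excluded]
            out["chromosomes"].append(d)
        return out


def load_genome_spec(source: Union[str, Path, Mapping]) -> GenomeSpec:
    """Load a :class:`GenomeSpec` from a YAML file or an equivalent mapping.

    The dialect is a mapping with keys ``system`` ("XY" or "ZW") and
    ``chromosomes`` (list of mappings with ``id``, ``length``, ``role`` and
    optional ``effective_length``); it round-trips through
    :func:`save_genome_spec`.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
    if not isinstance(data, Mapping) or "system" not in data or "chromosomes" not in data:
        raise GenomeSpecError("genome spec must define 'system' and 'chromosomes'")
    records = []
    for entry in data["chromosomes"]:
        records.append(
            ChromRecord(
                id=str(entry["id"]),
                length=int(entry["length"]),
                role=Role(str(entry.get("role", "autosome")).lower()),
                effective_length=entry.get("effective_length"),
                excluded=tuple(tuple(iv) for iv in entry.get("excluded", ())),
            )
        )
    return GenomeSpec(system=SexSystem(str(data["system"]).upper()), chromosomes=tuple(records))


def save_genome_spec(spec: GenomeSpec, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def spec_from_scaffolds(
    scaffold_ids: Sequence[str],
    lengths: Mapping[str, int],
    system: SexSystem,
    homogametic_id: str,
    heterogametic_id: str,
) -> GenomeSpec:
    """Build a spec from a plain scaffold list plus per-scaffold lengths.

    Listed scaffolds other than the two designated sex chromosomes become
    autosomes; scaffolds absent from the list are simply not part of the
    spec (the scaffold list is the inclusion filter).
    """
    if homogametic_id not in scaffold_ids or heterogametic_id not in scaffold_ids:
        raise MissingSexChromosomeError(
            f"sex chromosomes {homogametic_id!r}/{heterogametic_id!r} must appear in the scaffold list"
        )
    records = []
    for sid in scaffold_ids:
        if sid not in lengths:
            raise GenomeSpecError(f"no length known for scaffold {sid!r}")
        if sid == homogametic_id:
            role = Role.SEX_HOMOGAMETIC
        elif sid == heterogametic_id:
            role = Role.SEX_HETEROGAMETIC
        else:
            role = Role.AUTOSOME
        records.append(ChromRecord(id=sid, length=int(lengths[sid]), role=role))
    return GenomeSpec(system=SexSystem(system), chromosomes=tuple(records))


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


def _span(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(b - a for a, b in intervals)


def apply_exclusion_regions(
    spec: GenomeSpec, regions: Iterable[tuple[str, int, int]]
) -> GenomeSpec:
    """Reduce effective lengths by merged excluded spans (BED convention).

    Intervals are 0-based half-open ``(chrom, start, end)``.  Overlapping
    intervals are merged before subtraction, and intervals already recorded
    on a chromosome contribute nothing new, so applying the same region set
    twice is a no-op.  Counts are never modified.
    """
    regions = list(regions)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    ids = {c.id for c in spec.chromosomes}
    for chrom, start, end in regions:
        if chrom not in ids:
            raise ExclusionRegionError(f"exclusion region on unknown chromosome {chrom!r}")
        start, end = int(start), int(end)
        if end <= start or start < 0:
            raise ExclusionRegionError(
                f"invalid interval [{start}, {end}) on {chrom}: end must exceed start >= 0"
            )
        if end > spec.record(chrom).length:
            raise ExclusionRegionError(
                f"interval [{start}, {end}) extends beyond {chrom} "
                f"(length {spec.record(chrom).length})"
            )
        by_chrom.setdefault(chrom, []).append((start, end))

    new_records = []
    for rec in spec.chromosomes:
        if rec.id not in by_chrom:
            new_records.append(rec)
            continue
        combined = _merge_intervals(tuple(by_chrom[rec.id]) + rec.excluded)
        added = _span(combined) - _span(rec.excluded)
        eff = rec.effective_length - added
        if eff < 1:
            raise ExclusionRegionError(
                f"excluding {_span(combined)} bp from {rec.id} leaves no effective sequence"
            )
        new_records.append(replace(rec, effective_length=eff, excluded=combined))
    return GenomeSpec(system=spec.system, chromosomes=tuple(new_records))


def read_bed(path: Union[str, Path]) -> list[tuple[str, int, int]]:
    """Read the first three columns of a BED file (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ExclusionRegionError(f"BED line has fewer than 3 columns: {line!r}")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def read_scaffold_list(path: Union[str, Path]) -> list[str]:
    """Read a plain-text scaffold list, one ID per line; '#' lines are comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def bundled_spec(name: str) -> GenomeSpec:
    """Load one of the bundled example genome specs.

    Available: ``human`` (GRCh38-style 22 autosomes + X + Y), ``mouse``
    (19 autosomes + X + Y) and ``chicken`` (33 autosomes + Z + W).  These
    carry published assembly chromosome lengths as conveniences; they are
    not normative.
    """
    fname = {"human": "human_xy.yaml", "mouse": "mouse_xy.yaml", "chicken": "chicken_zw.yaml"}
    if name not in fname:
        raise KeyError(f"unknown bundled spec {name!r}; choose from {sorted(fname)}")
    ref = resources.files("metasex.data").joinpath(fname[name])
    return load_genome_spec(yaml.safe_load(ref.read_text()))
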