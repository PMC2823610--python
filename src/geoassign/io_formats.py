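"""Genotype and sampling-site file I/O.

The genotype dialect is the whitespace-delimited two-line-per-individual
layout used by spatial assignment programs: each individual occupies two
consecutive lines, both starting with the sample id and the sampling-site
index (``-1`` for unknown origin), followed by one allele call per locus.
Diploid loci carry one allele on each line; haploid pseudo-loci carry their
single allele on the first line and the missing sentinel on the second.
``-999`` marks a missing call throughout.

Sampling sites are one line each: ``code index latitude longitude zone``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

__all__ = [
    "MISSING",
    "NORTH",
    "SOUTH",
    "TRANSITION",
    "ZONES",
    "HAPLOGROUP_LOCUS",
    "HAPLOGROUP_CODES",
    "HAPLOGROUP_LABELS",
    "UNKNOWN_HAPLOGROUP",
    "ScatFormatError",
    "SampleRecord",
    "GenotypeTable",
    "SamplingSite",
    "parse_scat_genotypes",
    "write_scat_genotypes",
    "filter_suitable",
    "encode_haplogroup_locus",
    "decode_haplogroup_locus",
    "read_sites",
    "write_sites",
]

logger = logging.getLogger(__name__)

#: Sentinel for a missing allele call.
MISSING = -999

NORTH = "North"
SOUTH = "South"
TRANSITION = "Transition"
ZONES = (NORTH, TRANSITION, SOUTH)

#: Name of the haploid pseudo-locus carrying the mtDNA haplogroup.
HAPLOGROUP_LOCUS = "haplogroup"

#: Fixed integer codes so encoded files are bit-reproducible.
HAPLOGROUP_CODES: Mapping[str, int] = {"1a": 1, "1b": 2, "2a": 3, "2b": 4, "2c": 5}
HAPLOGROUP_LABELS: Mapping[int, str] = {v: k for k, v in HAPLOGROUP_CODES.items()}
UNKNOWN_HAPLOGROUP = "unknown"


class ScatFormatError(ValueError):
    """Raised when a genotype or site file violates the dialect."""


@dataclass(frozen=True)
class SampleRecord:
    """One individual: id, site index, and per-locus allele calls.

    ``alleles[i]`` is a tuple whose length equals the ploidy of locus ``i``
    (2 for microsatellite loci, 1 for the haplogroup pseudo-locus).
    """

    id: str
    site_index: int
    alleles: tuple[tuple[int, ...], ...]

    @property
    def unknown_origin(self) -> bool:
        return self.site_index == -1

    def locus_typed(self, i: int) -> bool:
        """True when locus ``i`` has no missing sentinel."""
        return MISSING not in self.alleles[i]

    @property
    def typed_locus_count(self) -> int:
        return sum(self.locus_typed(i) for i in range(len(self.alleles)))


@dataclass(frozen=True)
class GenotypeTable:
    """Ordered collection of :class:`SampleRecord` over a shared locus panel."""

    loci: tuple[str, ...]
    ploidy: tuple[int, ...]
    samples: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.ploidy):
            raise ValueError("loci and ploidy lengths differ")
        if any(p not in (1, 2) for p in self.ploidy):
            raise ValueError("ploidy must be 1 or 2")
        seen: set[str] = set()
        for rec in self.samples:
            if rec.id in seen:
                raise ValueError(f"duplicate sample id {rec.id!r}")
            seen.add(rec.id)
            if len(rec.alleles) != len(self.loci):
                raise ValueError(
                    f"sample {rec.id!r} has {len(rec.alleles)} loci, expected {len(self.loci)}"
                )
            for i, pair in enumerate(rec.alleles):
                if len(pair) != self.ploidy[i]:
                    raise ValueError(
                        f"sample {rec.id!r} locus {self.loci[i]!r}: ploidy mismatch"
                    )
                for a in pair:
                    if a != MISSING and a <= 0:
                        raise ValueError(
                            f"sample {rec.id!r} locus {self.loci[i]!r}: "
                            f"allele {a} is neither positive nor the missing sentinel"
                        )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def diploid_indices(self) -> tuple[int, ...]:
        """Indices of the diploid (microsatellite) loci."""
        return tuple(i for i, p in enumerate(self.ploidy) if p == 2)

    def typed_diploid_count(self, rec: SampleRecord) -> int:
        return sum(rec.locus_typed(i) for i in self.diploid_indices)

    def sample_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.samples)

    def get(self, sample_id: str) -> SampleRecord:
        for rec in self.samples:
            if rec.id == sample_id:
                return rec
        raise KeyError(sample_id)

    def drop(self, sample_id: str) -> "GenotypeTable":
        """Table without ``sample_id`` (for leave-one-out refits)."""
        kept = tuple(r for r in self.samples if r.id != sample_id)
        if len(kept) == len(self.samples):
            raise KeyError(sample_id)
        return replace(self, samples=kept)

    def known_samples(self) -> tuple[SampleRecord, ...]:
        return tuple(r for r in self.samples if not r.unknown_origin)

    def unknown_samples(self) -> tuple[SampleRecord, ...]:
        return tuple(r for r in self.samples if r.unknown_origin)


@dataclass(frozen=True)
class SamplingSite:
    """Georeferenced reference site with a biogeographic zone label."""

    code: str
    index: int
    latitude: float
    longitude: float
    zone: str = NORTH

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ValueError(f"unknown zone {self.zone!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} out of range")

    def region(self, transition_region: str = NORTH) -> str:
        """Region label for region-level scoring.

        Transition-zone sites are scored in ``transition_region``
        (default North), which a caller may flip for sensitivity checks.
        """
        if self.zone == TRANSITION:
            if transition_region not in (NORTH, SOUTH):
                raise ValueError("transition_region must be North or South")
            return transition_region
        return self.zone


def _iter_lines(source: str | Path | IO[str] | Iterable[str]) -> Iterator[tuple[int, str]]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from _iter_lines(fh)
        return
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if line and not line.startswith("#"):
            yield lineno, line


def parse_scat_genotypes(
    source: str | Path | IO[str] | Iterable[str],
    loci: Iterable[str] | None = None,
    haploid_loci: Iterable[str] = (),
) -> GenotypeTable:
    """Parse a two-line-per-individual genotype file.

    Parameters
    ----------
    source
        Path, open text stream, or iterable of lines.
    loci
        Optional locus names; defaults to ``L1..Ln`` with the trailing
        haploid pseudo-locus named :data:`HAPLOGROUP_LOCUS` when declared.
    haploid_loci
        Names of loci to treat as haploid.  The file still has two lines
        per individual; the second-line entry for a haploid locus must be
        the missing sentinel.
    """
    lines = list(_iter_lines(source))
    if len(lines) % 2:
        raise ScatFormatError(
            f"odd number of genotype lines ({len(lines)}): individuals must occupy line pairs"
        )
    if not lines:
        return GenotypeTable(loci=tuple(loci or ()), ploidy=(), samples=())

    first_tokens = lines[0][1].split()
    n_loci = len(first_tokens) - 2
    if n_loci < 1:
        raise ScatFormatError(f"line {lines[0][0]}: expected id, site index and >=1 locus")

    if loci is None:
        names: list[str] = [f"L{i + 1}" for i in range(n_loci)]
        haploid = set(haploid_loci)
        if haploid:
            # conventionally the pseudo-locus is last; rename it so the
            # declared haploid names resolve
            if len(haploid) == 1 and next(iter(haploid)) not in names:
                names[-1] = next(iter(haploid))
    else:
        names = list(loci)
        if len(names) != n_loci:
            raise ScatFormatError(
                f"{len(names)} locus names given but file has {n_loci} locus columns"
            )
        haploid = set(haploid_loci)
    unknown = haploid - set(names)
    if unknown:
        raise ScatFormatError(f"haploid loci not in locus panel: {sorted(unknown)}")
    ploidy = tuple(1 if name in haploid else 2 for name in names)

    def parse_line(lineno: int, line: str) -> tuple[str, int, list[int]]:
        tokens = line.split()
        if len(tokens) != n_loci + 2:
            raise ScatFormatError(
                f"line {lineno}: expected {n_loci + 2} fields, found {len(tokens)}"
            )
        sid = tokens[0]
        try:
            site_index = int(tokens[1])
        except ValueError as exc:
            raise ScatFormatError(f"line {lineno}: site index {tokens[1]!r} is not an integer") from exc
        calls = []
        for tok in tokens[2:]:
            try:
                calls.append(int(tok))
            except ValueError as exc:
                raise ScatFormatError(f"line {lineno}: allele token {tok!r} is not an integer") from exc
        return sid, site_index, calls

    samples: list[SampleRecord] = []
    for (ln1, raw1), (ln2, raw2) in zip(lines[::2], lines[1::2]):
        id1, site1, calls1 = parse_line(ln1, raw1)
        id2, site2, calls2 = parse_line(ln2, raw2)
        if id1 != id2 or site1 != site2:
            raise ScatFormatError(
                f"lines {ln1}/{ln2}: pair mismatch ({id1!r}@{site1} vs {id2!r}@{site2})"
            )
        alleles: list[tuple[int, ...]] = []
        for i, p in enumerate(ploidy):
            if p == 2:
                alleles.append((calls1[i], calls2[i]))
            else:
                if calls2[i] != MISSING:
                    raise ScatFormatError(
                        f"line {ln2}: haploid locus {names[i]!r} must carry the "
                        f"missing sentinel on the second line, found {calls2[i]}"
                    )
                alleles.append((calls1[i],))
        samples.append(SampleRecord(id=id1, site_index=site1, alleles=tuple(alleles)))

    return GenotypeTable(loci=tuple(names), ploidy=ploidy, samples=tuple(samples))


def write_scat_genotypes(table: GenotypeTable, dest: str | Path | IO[str]) -> None:
    """Write ``table`` in the two-line-per-individual dialect."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            write_scat_genotypes(table, fh)
        return
    for rec in table.samples:
        line1 = [rec.id, str(rec.site_index)]
        line2 = [rec.id, str(rec.site_index)]
        for pair in rec.alleles:
            line1.append(str(pair[0]))
            line2.append(str(pair[1]) if len(pair) == 2 else str(MISSING))
        dest.write(" ".join(line1) + "\n")
        dest.write(" ".join(line2) + "\n")


def filter_suitable(
    table: GenotypeTable, min_loci: int = 6
) -> tuple[GenotypeTable, list[str]]:
    """Keep samples typed at ``min_loci`` or more microsatellite loci.

    The haploid haplogroup pseudo-locus never counts toward the threshold.
    Returns the filtered table and the ids of excluded samples.
    """
    if min_loci < 1:
        raise ValueError("min_loci must be >= 1")
    if not table.samples:
        logger.warning("filter_suitable called on an empty table")
        return table, []
    kept = []
    excluded = []
    for rec in table.samples:
        if table.typed_diploid_count(rec) >= min_loci:
            kept.append(rec)
        else:
            excluded.append(rec.id)
    return replace(table, samples=tuple(kept)), excluded


def encode_haplogroup_locus(
    table: GenotypeTable, labels: Mapping[str, str]
) -> GenotypeTable:
    """Append the haplogroup as a haploid pseudo-locus.

    ``labels`` maps every sample id to one of ``1a/1b/2a/2b/2c`` or
    ``unknown`` (encoded as missing).
    """
    if HAPLOGROUP_LOCUS in table.loci:
        raise ValueError("table already carries the haplogroup pseudo-locus")
    missing_ids = [r.id for r in table.samples if r.id not in labels]
    if missing_ids:
        raise KeyError(f"no haplogroup label for samples: {missing_ids}")
    new_samples = []
    for rec in table.samples:
        label = labels[rec.id]
        if label == UNKNOWN_HAPLOGROUP:
            code = MISSING
        else:
            try:
                code = HAPLOGROUP_CODES[label]
            except KeyError as exc:
                raise ValueError(f"unknown haplogroup label {label!r}") from exc
        new_samples.append(replace(rec, alleles=rec.alleles + ((code,),)))
    return GenotypeTable(
        loci=table.loci + (HAPLOGROUP_LOCUS,),
        ploidy=table.ploidy + (1,),
        samples=tuple(new_samples),
    )


def decode_haplogroup_locus(table: GenotypeTable) -> dict[str, str]:
    """Inverse of :func:`encode_haplogroup_locus`: recover the label map."""
    try:
        i = table.loci.index(HAPLOGROUP_LOCUS)
    except ValueError as exc:
        raise ValueError("table has no haplogroup pseudo-locus") from exc
    out = {}
    for rec in table.samples:
        code = rec.alleles[i][0]
        out[rec.id] = UNKNOWN_HAPLOGROUP if code == MISSING else HAPLOGROUP_LABELS[code]
    return out


def read_sites(source: str | Path | IO[str] | Iterable[str]) -> tuple[SamplingSite, ...]:
    """Read a site file: ``code index latitude longitude zone`` per line.

    Indices must be unique and contiguous from 1; sites are returned in
    index order.
    """
    sites = []
    for lineno, line in _iter_lines(source):
        tokens = line.split()
        if len(tokens) != 5:
            raise ScatFormatError(f"site line {lineno}: expected 5 fields, found {len(tokens)}")
        code, idx, lat, lon, zone = tokens
        try:
            site = SamplingSite(
                code=code,
                index=int(idx),
                latitude=float(lat),
                longitude=float(lon),
                zone=zone,
            )
        except ValueError as exc:
            raise ScatFormatError(f"site line {lineno}: {exc}") from exc
        sites.append(site)
    sites.sort(key=lambda s: s.index)
    indices = [s.index for s in sites]
    if indices != list(range(1, len(sites) + 1)):
        raise ScatFormatError(f"site indices must be contiguous from 1, got {indices}")
    return tuple(sites)


def write_sites(sites: Iterable[SamplingSite], dest: str | Path | IO[str]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            write_sites(sites, fh)
        return
    for s in sites:
        dest.write(f"{s.code} {s.index} {s.latitude:.6f} {s.longitude:.6f} {s.zone}\n")
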