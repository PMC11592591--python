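"""Amplicon target definitions for the bcfDNA assay.

An :class:`AmpliconTarget` describes one PCR amplicon over a genomic region
with brain-specific methylation: the unconverted top-strand reference, the
primer sequences as they appear in sequenced reads, the CpG positions
interrogated, and the direction of the brain-specific epihaplotype
(fully methylated or fully unmethylated).

Amplicons are kept at 170 bp or shorter so that they remain compatible with
the typical ~167 bp length of circulating cell-free DNA fragments.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

MAX_AMPLICON_LENGTH = 170

#: brain-specific epihaplotype directions
ALL_METHYLATED = "all-methylated"
ALL_UNMETHYLATED = "all-unmethylated"


def stable_hash(text: str) -> int:
    """Deterministic 32-bit hash of a string (stable across processes)."""
    return zlib.crc32(text.encode("utf-8"))


def bisulfite_convert(seq: str, methylated_offsets: set[int] | frozenset[int] = frozenset()) -> str:
    """Return the bisulfite image of the top strand.

    Every cytosine converts to thymine except those at ``methylated_offsets``
    (CpG cytosines protected by methylation).
    """
    out = list(seq.upper())
    for i, base in enumerate(out):
        if base == "C" and i not in methylated_offsets:
            out[i] = "T"
    return "".join(out)


@dataclass(frozen=True)
class AmpliconTarget:
    """One target region of the assay.

    Parameters
    ----------
    name
        Target identifier (gene symbol or array probe id).
    reference_sequence
        Unconverted genomic top strand of the full amplicon, primers included.
    fwd_primer, rev_primer
        Primer sequences as they appear at the 5' and 3' ends of a sequenced
        read (i.e. on the bisulfite-converted top strand).
    cpg_offsets
        0-based offsets of the C of each CpG dinucleotide in
        ``reference_sequence``, strictly increasing.
    brain_epihap_direction
        ``"all-methylated"`` or ``"all-unmethylated"``: which homogeneous
        epihaplotype marks brain-derived molecules at this target.
    """

    name: str
    reference_sequence: str
    fwd_primer: str
    rev_primer: str
    cpg_offsets: tuple[int, ...]
    brain_epihap_direction: str = ALL_UNMETHYLATED

    def __post_init__(self) -> None:
        seq = self.reference_sequence.upper()
        object.__setattr__(self, "reference_sequence", seq)
        object.__setattr__(self, "cpg_offsets", tuple(int(o) for o in self.cpg_offsets))
        if len(seq) > MAX_AMPLICON_LENGTH:
            raise ValueError(
                f"{self.name}: amplicon length {len(seq)} exceeds {MAX_AMPLICON_LENGTH} bp"
            )
        if len(self.cpg_offsets) < 2:
            raise ValueError(f"{self.name}: a target needs at least 2 CpG sites")
        if list(self.cpg_offsets) != sorted(set(self.cpg_offsets)):
            raise ValueError(f"{self.name}: CpG offsets must be strictly increasing")
        for off in self.cpg_offsets:
            if not 0 <= off < len(seq) - 1 or seq[off : off + 2] != "CG":
                raise ValueError(
                    f"{self.name}: offset {off} does not address the C of a CG dinucleotide"
                )
        if self.brain_epihap_direction not in (ALL_METHYLATED, ALL_UNMETHYLATED):
            raise ValueError(f"{self.name}: unknown direction {self.brain_epihap_direction!r}")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)

    @property
    def length(self) -> int:
        return len(self.reference_sequence)

    @property
    def primer_cpg_indices(self) -> tuple[int, ...]:
        """Indices (into ``cpg_offsets``) of CpGs lying within a primer.

        Primer-resident CpGs carry the primer-dictated base in every read, not
        the molecule's methylation state, and must be trimmed before
        epihaplotype analysis.
        """
        lo = len(self.fwd_primer)
        hi = self.length - len(self.rev_primer)
        return tuple(i for i, off in enumerate(self.cpg_offsets) if off < lo or off >= hi)

    @property
    def interior_cpg_indices(self) -> tuple[int, ...]:
        primer = set(self.primer_cpg_indices)
        return tuple(i for i in range(self.n_cpgs) if i not in primer)

    def brain_epihaplotype(self, trimmed: bool = True) -> str:
        """The brain-specific epihaplotype string for this target."""
        symbol = "1" if self.brain_epihap_direction == ALL_METHYLATED else "0"
        n = len(self.interior_cpg_indices) if trimmed else self.n_cpgs
        return symbol * n

    def converted_reference(self, epihaplotype: str | None = None) -> str:
        """Bisulfite image of the reference under an epihaplotype.

        ``None`` means fully unmethylated (every C reads as T).
        """
        if epihaplotype is None:
            meth: frozenset[int] = frozenset()
        else:
            if len(epihaplotype) != self.n_cpgs:
                raise ValueError("epihaplotype length does not match CpG count")
            meth = frozenset(
                off for off, state in zip(self.cpg_offsets, epihaplotype) if state == "1"
            )
        return bisulfite_convert(self.reference_sequence, meth)


@dataclass
class TargetPanel:
    """An ordered collection of amplicon targets keyed by name."""

    targets: list[AmpliconTarget] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.name for t in self.targets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate target names in panel")

    def __iter__(self):
        return iter(self.targets)

    def __len__(self) -> int:
        return len(self.targets)

    def __getitem__(self, name: str) -> AmpliconTarget:
        for t in self.targets:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.targets]

    def to_yaml(self, path: str | Path) -> None:
        payload = [
            {
                "name": t.name,
                "reference_sequence": t.reference_sequence,
                "fwd_primer": t.fwd_primer,
                "rev_primer": t.rev_primer,
                "cpg_offsets": list(t.cpg_offsets),
                "brain_epihap_direction": t.brain_epihap_direction,
            }
            for t in self.targets
        ]
        Path(path).write_text(yaml.safe_dump({"targets": payload}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TargetPanel":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            targets=[
                AmpliconTarget(
                    name=d["name"],
                    reference_sequence=d["reference_sequence"],
                    fwd_primer=d["fwd_primer"],
                    rev_primer=d["rev_primer"],
                    cpg_offsets=tuple(d["cpg_offsets"]),
                    brain_epihap_direction=d["brain_epihap_direction"],
                )
                for d in payload["targets"]
            ]
        )


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=length))


def _scrub_cpgs(seq: list[str]) -> None:
    """Remove accidental CG dinucleotides in place (G -> A)."""
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A"


def _make_target(
    rng: np.random.Generator,
    name: str,
    length: int,
    primer_len: int,
    cpg_offsets: tuple[int, ...],
    direction: str,
) -> AmpliconTarget:
    seq = _random_sequence(rng, length)
    _scrub_cpgs(seq)
    for off in cpg_offsets:
        seq[off] = "C"
        seq[off + 1] = "G"
    _scrub_cpgs_outside(seq, cpg_offsets)
    ref = "".join(seq)
    fwd = bisulfite_convert(ref[:primer_len])
    rev = bisulfite_convert(ref[length - primer_len :])
    return AmpliconTarget(
        name=name,
        reference_sequence=ref,
        fwd_primer=fwd,
        rev_primer=rev,
        cpg_offsets=cpg_offsets,
        brain_epihap_direction=direction,
    )


def _scrub_cpgs_outside(seq: list[str], keep: tuple[int, ...]) -> None:
    keep_set = set(keep)
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in keep_set:
            seq[i + 1] = "A"


def build_default_panel(seed: int = 20_2541) -> TargetPanel:
    """Construct the default five-target assay panel with synthetic sequences.

    The panel follows the bcfDNA assay layout: one target
    hypermethylated in brain (APC2, brain epihaplotype fully methylated) and
    four hypomethylated in brain (PACRG, FAM123, cg02619656, cg09787504,
    brain epihaplotype fully unmethylated). Reference sequences are synthetic
    stand-ins generated deterministically; CpG counts and amplicon lengths are
    in the realistic range for 170 bp cfDNA-compatible amplicons.

    APC2 carries one CpG inside the forward primer and PACRG one inside the
    reverse primer, exercising primer-CpG trimming.
    """
    rng = np.random.default_rng(seed)
    spec = [
        # name, length, cpg offsets, direction
        ("APC2", 160, (10, 38, 55, 79, 102, 121, 133), ALL_METHYLATED),
        ("PACRG", 150, (30, 52, 68, 90, 112, 138), ALL_UNMETHYLATED),
        ("FAM123", 156, (28, 47, 71, 95, 118, 129), ALL_UNMETHYLATED),
        ("cg02619656", 144, (25, 49, 66, 88, 110), ALL_UNMETHYLATED),
        ("cg09787504", 166, (33, 58, 84, 107, 126, 140), ALL_UNMETHYLATED),
    ]
    targets = [
        _make_target(rng, name, length, 20, offsets, direction)
        for name, length, offsets, direction in spec
    ]
    return TargetPanel(targets)
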