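"""Shared genomic data model.

All genomic intervals are 0-based, half-open (BED convention).  A gene is
anchored by a single TSS coordinate and a strand; nucleosome positioning
sites are strandless intervals summarised by their integer centre
``floor((start + end) / 2)``; chromatin-state domains are labelled intervals
drawn from a fixed state alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RESISTANT = "resistant"
SENSITIVE = "sensitive"
SENSITIVITIES = (RESISTANT, SENSITIVE)

#: Four-state chromatin alphabet (hidden-Markov segmentation of S2 chromatin).
FOUR_STATE_ALPHABET = frozenset({"Aquamarine", "Lazurite", "Malachite", "Ruby"})
#: Five-state chromatin alphabet (whole-genome protein-occupancy segmentation).
FIVE_STATE_ALPHABET = frozenset({"Yellow", "Red", "Green", "Blue", "Black"})


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene with one distinct TSS and its expression vector.

    Parameters
    ----------
    gene_id
        Unique identifier within a gene table.
    chrom
        Chromosome (arm) name.
    tss
        0-based genomic coordinate of the transcription start site.
    strand
        ``"+"`` or ``"-"``.
    rpkm_s2
        Expression level in S2 cells (reads per kilobase million), >= 0.
    rpkm_tissues
        Per-tissue RPKM values, one entry per profiled tissue.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    rpkm_s2: float
    rpkm_tissues: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.rpkm_s2 < 0:
            raise ValueError(f"gene {self.gene_id}: negative rpkm_s2 {self.rpkm_s2}")
        if any(v < 0 for v in self.rpkm_tissues):
            raise ValueError(f"gene {self.gene_id}: negative tissue RPKM value")


@dataclass(frozen=True)
class NucleosomeSite:
    """A nucleosome positioning site called from an MNase digestion map."""

    chrom: str
    start: int
    end: int
    sensitivity: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid site interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.sensitivity not in SENSITIVITIES:
            raise ValueError(f"unknown sensitivity class {self.sensitivity!r}")

    @property
    def center(self) -> int:
        """Integer site centre, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ChromatinDomain:
    """A labelled chromatin-state domain (half-open interval)."""

    chrom: str
    start: int
    end: int
    state: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid domain interval [{self.start}, {self.end}) on {self.chrom}"
            )


@dataclass(frozen=True)
class StateMapping:
    """Partition of a chromatin-state alphabet into Active and Non-Active states."""

    active_states: frozenset[str]
    inactive_states: frozenset[str]

    def __post_init__(self) -> None:
        if self.active_states & self.inactive_states:
            raise ValueError("active and inactive state sets must be disjoint")
        if not self.active_states or not self.inactive_states:
            raise ValueError("both state groups must be non-empty")

    @property
    def alphabet(self) -> frozenset[str]:
        return self.active_states | self.inactive_states


#: Aquamarine is the open (Active) state; Lazurite/Malachite/Ruby are Non-Active.
FOUR_STATE_MAPPING = StateMapping(
    active_states=frozenset({"Aquamarine"}),
    inactive_states=frozenset({"Lazurite", "Malachite", "Ruby"}),
)

#: Yellow/Red are Active; Green/Blue/Black are Non-Active.
FILION_MAPPING = StateMapping(
    active_states=frozenset({"Yellow", "Red"}),
    inactive_states=frozenset({"Green", "Blue", "Black"}),
)

STATE_MAPPINGS = {"4hmm": FOUR_STATE_MAPPING, "filion": FILION_MAPPING}
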