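"""Domain types shared by the store, grouping and rendering layers.

Coordinate convention: genomic positions are 1-based and region endpoints are
inclusive at both ends, matching the Illumina manifest convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AnnotationError, BetascopeError

#: Number of probes interrogated by the full 450k-style array.
FULL_ARRAY_PROBE_COUNT = 485_577

ISLAND_CLASSES = ("high_density", "intermediate_density", "none")
STRANDS = ("+", "-", "unknown")

#: Metadata key names with cross-project meaning.
RESERVED_KEYS = ("project", "tissuetype")

Scalar = str | int | float | bool


@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic location and reliability flags for a single array probe."""

    probe_id: str
    chromosome: str
    position: int
    strand: str = "unknown"
    genes: tuple[str, ...] = ()
    island_class: str = "none"
    snp_in_probe: bool = False
    snp_at_cpg: bool = False
    reliable: bool = True

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise AnnotationError("probe_id must be non-empty")
        if not isinstance(self.position, int) or self.position < 1:
            raise AnnotationError(
                f"probe {self.probe_id!r}: position must be an integer >= 1, got {self.position!r}"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(
                f"probe {self.probe_id!r}: strand must be one of {STRANDS}, got {self.strand!r}"
            )
        if self.island_class not in ISLAND_CLASSES:
            raise AnnotationError(
                f"probe {self.probe_id!r}: island_class must be one of {ISLAND_CLASSES}, "
                f"got {self.island_class!r}"
            )
        object.__setattr__(self, "genes", tuple(self.genes))

    def to_doc(self) -> dict:
        return {
            "probe_id": self.probe_id,
            "chromosome": self.chromosome,
            "position": self.position,
            "strand": self.strand,
            "genes": list(self.genes),
            "island_class": self.island_class,
            "snp_in_probe": self.snp_in_probe,
            "snp_at_cpg": self.snp_at_cpg,
            "reliable": self.reliable,
        }

    @classmethod
    def from_doc(cls, doc: dict) -> "ProbeAnnotation":
        return cls(
            probe_id=doc["probe_id"],
            chromosome=doc["chromosome"],
            position=int(doc["position"]),
            strand=doc.get("strand", "unknown"),
            genes=tuple(doc.get("genes", ())),
            island_class=doc.get("island_class", "none"),
            snp_in_probe=bool(doc.get("snp_in_probe", False)),
            snp_at_cpg=bool(doc.get("snp_at_cpg", False)),
            reliable=bool(doc.get("reliable", True)),
        )


@dataclass(frozen=True)
class SampleRecord:
    """Free-form key-value metadata for one sample.

    Absent keys are truly absent from ``metadata``; no null placeholders are
    ever stored. ``project`` and ``tissuetype`` are reserved key names with
    cross-project meaning; ``project`` lives on the record itself.
    """

    sample_id: str
    project: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise BetascopeError("sample_id must be non-empty")
        if not self.project:
            raise BetascopeError(f"sample {self.sample_id!r}: project must be non-empty")
        for k, v in self.metadata.items():
            if v is None:
                raise BetascopeError(
                    f"sample {self.sample_id!r}: key {k!r} is null; omit absent keys instead"
                )
            if not isinstance(v, (str, int, float, bool)):
                raise BetascopeError(
                    f"sample {self.sample_id!r}: key {k!r} has non-scalar value {v!r}"
                )

    def get_value(self, key: str) -> Scalar | None:
        """Resolve a grouping key: 'project' comes from the record, anything
        else from the metadata map. Returns None when the key is absent."""
        if key == "project":
            return self.project
        return self.metadata.get(key)

    def to_doc(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "project": self.project,
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_doc(cls, doc: dict) -> "SampleRecord":
        return cls(
            sample_id=doc["sample_id"],
            project=doc["project"],
            metadata=dict(doc.get("metadata", {})),
        )


@dataclass(frozen=True)
class GenomicRegion:
    """1-based genomic interval, inclusive at both ends."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise BetascopeError(f"region start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise BetascopeError(
                f"region start {self.start} exceeds end {self.end} on {self.chromosome}"
            )

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProbeBetaDocument:
    """All beta values for one probe within one project — the unit of storage.

    Document count therefore scales with projects x probes, never with the
    number of samples.
    """

    project: str
    probe_id: str
    chromosome: str
    position: int
    betas: dict = field(default_factory=dict)  # sample_id -> beta in [0, 1]

    def to_doc(self) -> dict:
        return {
            "project": self.project,
            "probe_id": self.probe_id,
            "chromosome": self.chromosome,
            "position": self.position,
            "betas": dict(self.betas),
        }

    @classmethod
    def from_doc(cls, doc: dict) -> "ProbeBetaDocument":
        return cls(
            project=doc["project"],
            probe_id=doc["probe_id"],
            chromosome=doc["chromosome"],
            position=int(doc["position"]),
            betas={k: float(v) for k, v in doc.get("betas", {}).items()},
        )


@dataclass
class RegionDataset:
    """Annotation-joined per-sample betas over a genomic window.

    ``probes`` is ordered by ascending position (ties broken by probe_id) and
    pairs each annotation with a sample_id -> beta map. This is the renderer's
    input.
    """

    region: GenomicRegion
    probes: list  # list[tuple[ProbeAnnotation, dict[str, float]]]
    samples: list  # list[SampleRecord]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def n_values(self) -> int:
        return sum(len(betas) for _, betas in self.probes)
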