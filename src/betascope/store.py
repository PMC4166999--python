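"""Document-oriented storage of beta values, sample metadata and annotation.

Beta values are held in one document per (project, probe), so the document
count scales with the number of projects, not with the number of samples.
Backends are pluggable behind a small key-value + scan contract; the default
backend persists each collection as a JSON-lines file so no database server
is needed.
"""

from __future__ import annotations

import bisect
import json
import os
import re
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass

from .errors import (
    BetaRangeError,
    DuplicateProbeError,
    DuplicateSampleError,
    LocusError,
    MetadataError,
    StoreError,
    UnknownBackendError,
    UnknownProjectError,
    UnknownSampleError,
)
from .types import (
    GenomicRegion,
    ProbeAnnotation,
    ProbeBetaDocument,
    RegionDataset,
    SampleRecord,
)

COLLECTIONS = ("annotation", "samples", "betas")

# Primary-key fields per collection; backends derive storage keys from these.
_KEY_FIELDS = {
    "annotation": ("probe_id",),
    "samples": ("project", "sample_id"),
    "betas": ("project", "probe_id"),
}

_LOCUS_FORMS = (
    'a coordinate "chrN:start-end" (commas permitted)',
    "a probe id present in the annotation",
    "a gene name present in the annotation (case-insensitive)",
)


def _doc_key(collection: str, doc: Mapping) -> tuple:
    return tuple(doc[f] for f in _KEY_FIELDS[collection])


class MemoryBackend:
    """Ephemeral in-process backend; contents vanish when the handle dies."""

    name = "memory"

    def __init__(self, path=None):
        self._data = {c: {} for c in COLLECTIONS}
        self._dirty: set[str] = set()

    def get(self, collection: str, key: tuple):
        return self._data[collection].get(key)

    def put(self, collection: str, key: tuple, doc: dict) -> None:
        self._data[collection][key] = doc
        self._dirty.add(collection)

    def touch(self, collection: str) -> None:
        """Mark a collection dirty after in-place document mutation."""
        self._dirty.add(collection)

    def scan(self, collection: str) -> Iterator[dict]:
        yield from self._data[collection].values()

    def count(self, collection: str) -> int:
        return len(self._data[collection])

    def clear(self) -> None:
        for c in COLLECTIONS:
            self._data[c].clear()

    def flush(self) -> None:  # nothing to persist
        pass


class FileBackend(MemoryBackend):
    """JSON-lines-on-disk backend: one file per collection under a directory.

    The whole store is held in memory and rewritten atomically on flush; this
    is the desk-scale trade-off (a full-array project is a few hundred MB at
    most) and keeps every test independent of a database server.
    """

    name = "file"
    _MARKER = "betascope.json"

    def __init__(self, path):
        super().__init__()
        if path is None:
            raise StoreError("file backend requires a path")
        self.path = str(path)
        marker = os.path.join(self.path, self._MARKER)
        if os.path.exists(self.path):
            if not os.path.isdir(self.path):
                raise StoreError(f"store path {self.path!r} exists and is not a directory")
            if os.listdir(self.path) and not os.path.exists(marker):
                raise StoreError(
                    f"directory {self.path!r} is non-empty and is not a betascope store"
                )
        else:
            os.makedirs(self.path)
        if os.path.exists(marker):
            self._load()
        else:
            with open(marker, "w", encoding="utf-8") as fh:
                json.dump({"format": "betascope-store", "version": 1}, fh)
                fh.write("\n")
            self.flush()

    def _file(self, collection: str) -> str:
        return os.path.join(self.path, f"{collection}.jsonl")

    def _load(self) -> None:
        for collection in COLLECTIONS:
            fname = self._file(collection)
            if not os.path.exists(fname):
                continue
            data = self._data[collection]
            with open(fname, encoding="utf-8") as fh:
                for lineno, line in enumerate(fh, 1):
                    line = line.strip()
                    if not line:
                        continue
                    try:
                        doc = json.loads(line)
                    except json.JSONDecodeError as exc:
                        raise StoreError(
                            f"corrupt store: {fname} line {lineno}: {exc}"
                        ) from exc
                    data[_doc_key(collection, doc)] = doc

    def flush(self) -> None:
        for collection in COLLECTIONS:
            fname = self._file(collection)
            if collection not in self._dirty and os.path.exists(fname):
                continue
            tmp = fname + ".tmp"
            with open(tmp, "w", encoding="utf-8") as fh:
                for key in sorted(self._data[collection]):
                    fh.write(json.dumps(self._data[collection][key], sort_keys=True))
                    fh.write("\n")
            os.replace(tmp, fname)
        self._dirty.clear()


BACKENDS = {"file": FileBackend, "memory": MemoryBackend}


@dataclass
class DepositStats:
    n_written: int
    n_unannotated_skipped: int


def open_store(path=None, backend: str = "file") -> "Store":
    """Open (or create) a store at ``path`` using the named backend.

    Opening an existing store reopens it; it is never clobbered.
    """
    if backend not in BACKENDS:
        raise UnknownBackendError(
            f"unknown backend {backend!r}; valid backends: {', '.join(sorted(BACKENDS))}"
        )
    return Store(BACKENDS[backend](path))


class Store:
    """Handle exposing all store operations over a backend."""

    def __init__(self, backend):
        self._backend = backend
        self._position_index: dict[str, tuple[list[int], list[str]]] = {}
        self._gene_index: dict[str, list[str]] | None = None
        self._rebuild_indexes()

    # ------------------------------------------------------------------ index

    def _rebuild_indexes(self) -> None:
        """(chromosome -> parallel sorted position/probe lists) for interval
        queries; the gene index is built lazily on first gene lookup."""
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for doc in self._backend.scan("annotation"):
            by_chrom.setdefault(doc["chromosome"], []).append((doc["position"], doc["probe_id"]))
        self._position_index = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            self._position_index[chrom] = ([p for p, _ in pairs], [pid for _, pid in pairs])
        self._gene_index = None

    def _build_gene_index(self) -> dict[str, list[str]]:
        index: dict[str, list[str]] = {}
        for doc in self._backend.scan("annotation"):
            for gene in doc.get("genes", ()):
                index.setdefault(gene.upper(), []).append(doc["probe_id"])
        return index

    # ------------------------------------------------------------- annotation

    def load_annotation(self, records: Iterable[ProbeAnnotation]) -> int:
        """Load probe annotation; returns the number of records stored.

        The whole stream is validated before anything is written.
        """
        batch: dict[tuple, dict] = {}
        for rec in records:
            if not isinstance(rec, ProbeAnnotation):
                rec = ProbeAnnotation.from_doc(rec)
            key = (rec.probe_id,)
            if key in batch or self._backend.get("annotation", key) is not None:
                raise DuplicateProbeError(f"duplicate probe_id {rec.probe_id!r} in annotation")
            batch[key] = rec.to_doc()
        for key, doc in batch.items():
            self._backend.put("annotation", key, doc)
        self._backend.flush()
        self._rebuild_indexes()
        return len(batch)

    def get_annotation(self, probe_id: str) -> ProbeAnnotation | None:
        doc = self._backend.get("annotation", (probe_id,))
        return None if doc is None else ProbeAnnotation.from_doc(doc)

    def n_annotated_probes(self) -> int:
        return self._backend.count("annotation")

    # ---------------------------------------------------------------- samples

    def register_samples(self, project: str, records: Iterable[SampleRecord]) -> int:
        batch: dict[tuple, dict] = {}
        for rec in records:
            if rec.project != project:
                raise StoreError(
                    f"sample {rec.sample_id!r} declares project {rec.project!r}, "
                    f"expected {project!r}"
                )
            key = (project, rec.sample_id)
            if key in batch or self._backend.get("samples", key) is not None:
                raise DuplicateSampleError(
                    f"sample {rec.sample_id!r} already registered in project {project!r}"
                )
            batch[key] = rec.to_doc()
        for key, doc in batch.items():
            self._backend.put("samples", key, doc)
        self._backend.flush()
        return len(batch)

    def get_sample(self, project: str, sample_id: str) -> SampleRecord | None:
        doc = self._backend.get("samples", (project, sample_id))
        return None if doc is None else SampleRecord.from_doc(doc)

    def projects(self) -> list[str]:
        return sorted({doc["project"] for doc in self._backend.scan("samples")})

    def samples(self, project: str | None = None) -> list[SampleRecord]:
        records = [
            SampleRecord.from_doc(doc)
            for doc in self._backend.scan("samples")
            if project is None or doc["project"] == project
        ]
        records.sort(key=lambda r: (r.project, r.sample_id))
        return records

    def _require_project(self, project: str) -> None:
        if not any(doc["project"] == project for doc in self._backend.scan("samples")):
            raise UnknownProjectError(f"unknown project {project!r}")

    # ------------------------------------------------------------------ betas

    def deposit_betas(
        self, project: str, sample_id: str, values: Mapping[str, float]
    ) -> DepositStats:
        """Merge one sample's beta values into per-(project, probe) documents.

        Probes absent from the annotation are skipped and counted, not an
        error. Re-depositing a (project, sample, probe) overwrites.
        """
        self._require_project(project)
        if self._backend.get("samples", (project, sample_id)) is None:
            raise UnknownSampleError(
                f"sample {sample_id!r} is not registered in project {project!r}"
            )
        for probe_id, beta in values.items():
            if not isinstance(beta, (int, float)) or beta != beta or not 0.0 <= beta <= 1.0:
                raise BetaRangeError(
                    f"beta for probe {probe_id!r} is {beta!r}, outside [0, 1]"
                )
        n_written = 0
        n_skipped = 0
        for probe_id, beta in values.items():
            ann = self._backend.get("annotation", (probe_id,))
            if ann is None:
                n_skipped += 1
                continue
            key = (project, probe_id)
            doc = self._backend.get("betas", key)
            if doc is None:
                doc = {
                    "project": project,
                    "probe_id": probe_id,
                    "chromosome": ann["chromosome"],
                    "position": ann["position"],
                    "betas": {},
                }
                self._backend.put("betas", key, doc)
            doc["betas"][sample_id] = float(beta)
            n_written += 1
        if n_written:
            self._backend.touch("betas")
        self._backend.flush()
        return DepositStats(n_written=n_written, n_unannotated_skipped=n_skipped)

    def n_beta_documents(self) -> int:
        return self._backend.count("betas")

    # ---------------------------------------------------------------- queries

    def query_region(self, region: GenomicRegion, projects: list[str]) -> RegionDataset:
        """All probes in ``region`` carrying at least one beta value in the
        named projects, joined with their annotation, sorted by (position,
        probe_id). Endpoints are inclusive."""
        for project in projects:
            self._require_project(project)
        positions, probe_ids = self._position_index.get(region.chromosome, ([], []))
        lo = bisect.bisect_left(positions, region.start)
        hi = bisect.bisect_right(positions, region.end)
        candidates = sorted(
            zip(positions[lo:hi], probe_ids[lo:hi]), key=lambda t: (t[0], t[1])
        )
        probes = []
        sample_ids: set[str] = set()
        sample_project: dict[str, str] = {}
        for _, probe_id in candidates:
            merged: dict[str, float] = {}
            for project in projects:
                doc = self._backend.get("betas", (project, probe_id))
                if doc is None:
                    continue
                for sid, beta in doc["betas"].items():
                    if sample_project.setdefault(sid, project) != project:
                        raise StoreError(
                            f"sample id {sid!r} occurs in multiple queried projects; "
                            "qualify sample ids to query these projects together"
                        )
                    merged[sid] = float(beta)
            if merged:
                probes.append((self.get_annotation(probe_id), merged))
                sample_ids.update(merged)
        samples = [
            rec
            for project in sorted(set(projects))
            for rec in self.samples(project)
            if rec.sample_id in sample_ids
        ]
        return RegionDataset(region=region, probes=probes, samples=samples)

    _COORD_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")

    def resolve_locus(self, query: str, flank: int = 0) -> GenomicRegion:
        """Resolve a coordinate string, probe id, or gene name to a region.

        Probe ids take precedence over gene names when a string matches both.
        Probe/gene windows are widened by ``flank`` bp and clipped at 1.
        """
        query = query.strip()
        m = self._COORD_RE.match(query)
        if m:
            start = int(m.group("start").replace(",", ""))
            end = int(m.group("end").replace(",", ""))
            return GenomicRegion(m.group("chrom"), start, end)
        ann = self.get_annotation(query)
        if ann is not None:
            return GenomicRegion(
                ann.chromosome, max(1, ann.position - flank), ann.position + flank
            )
        if self._gene_index is None:
            self._gene_index = self._build_gene_index()
        probe_ids = self._gene_index.get(query.upper())
        if probe_ids:
            anns = [self.get_annotation(pid) for pid in probe_ids]
            chroms = {a.chromosome for a in anns}
            if len(chroms) > 1:
                raise LocusError(
                    f"gene {query!r} has probes on multiple chromosomes "
                    f"({', '.join(sorted(chroms))}); use a coordinate query"
                )
            lo = min(a.position for a in anns)
            hi = max(a.position for a in anns)
            return GenomicRegion(chroms.pop(), max(1, lo - flank), hi + flank)
        raise LocusError(
            f"could not resolve locus {query!r}; accepted forms: "
            + "; ".join(_LOCUS_FORMS)
        )

    # ----------------------------------------------------------- metadata fix

    def repair_metadata_key(self, project: str, old_key: str, new_key: str) -> int:
        """Rename ``old_key`` to ``new_key`` on every sample carrying it.

        All-or-nothing: if any carrier already has ``new_key``, nothing is
        modified.
        """
        self._require_project(project)
        if old_key == new_key:
            return 0
        carriers = []
        for doc in self._backend.scan("samples"):
            if doc["project"] != project or old_key not in doc["metadata"]:
                continue
            if new_key in doc["metadata"]:
                raise MetadataError(
                    f"sample {doc['sample_id']!r} already has key {new_key!r}; "
                    "no samples were modified"
                )
            carriers.append(doc)
        for doc in carriers:
            doc["metadata"][new_key] = doc["metadata"].pop(old_key)
        if carriers:
            self._backend.touch("samples")
        self._backend.flush()
        return len(carriers)

    def repair_metadata_value(
        self, project: str, key: str, old_value, new_value
    ) -> int:
        """Replace exact matches of ``old_value`` under ``key``; comparison is
        exact and type-strict ("Female" != "female", 1 != True)."""
        self._require_project(project)
        changed = 0
        for doc in self._backend.scan("samples"):
            if doc["project"] != project or key not in doc["metadata"]:
                continue
            current = doc["metadata"][key]
            if type(current) is type(old_value) and current == old_value:
                doc["metadata"][key] = new_value
                changed += 1
        if changed:
            self._backend.touch("samples")
            self._backend.flush()
        return changed

    # ----------------------------------------------------------- dump/restore

    def iter_documents(self) -> Iterator[dict]:
        """All documents, tagged with a ``_type`` discriminator, in a
        deterministic order (annotation, samples, betas; each key-sorted)."""
        for collection, type_name in (
            ("annotation", "annotation"),
            ("samples", "sample"),
            ("betas", "betas"),
        ):
            docs = sorted(self._backend.scan(collection), key=lambda d: _doc_key(collection, d))
            for doc in docs:
                out = {"_type": type_name}
                out.update(doc)
                yield out

    def dump(self) -> Iterator[str]:
        """Lossless JSON-lines export of the entire store."""
        for doc in self.iter_documents():
            yield json.dumps(doc, sort_keys=True)

    def restore(self, lines: Iterable[str]) -> int:
        """Load a dump stream into this store; returns documents restored."""
        n = 0
        for lineno, line in enumerate(lines, 1):
            line = line.strip()
            if not line:
                continue
            try:
                doc = json.loads(line)
                type_name = doc.pop("_type")
            except (json.JSONDecodeError, KeyError) as exc:
                raise StoreError(f"bad dump line {lineno}: {exc}") from exc
            collection = {"annotation": "annotation", "sample": "samples", "betas": "betas"}.get(
                type_name
            )
            if collection is None:
                raise StoreError(f"bad dump line {lineno}: unknown _type {type_name!r}")
            self._backend.put(collection, _doc_key(collection, doc), doc)
            n += 1
        self._backend.flush()
        self._rebuild_indexes()
        return n
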