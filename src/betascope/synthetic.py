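"""Seeded synthetic fixtures: annotation manifests, projects, metadata and
beta matrices with planted group structure.

Everything is deterministic given the seed and writes exactly the formats the
importers read, so the whole stack is testable without downloads. Background
betas follow a two-component mixture (low/high methylation) to mimic the
bimodal genome-wide beta landscape; planted effects draw clipped Gaussians
around group-specific means.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimulationError
from .importers import (
    BetaMatrix,
    GeneModel,
    write_annotation_csv,
    write_beta_csv,
    write_sample_json,
)
from .types import FULL_ARRAY_PROBE_COUNT, ProbeAnnotation, SampleRecord

#: Background beta mixture: (means, sds, weights).
BACKGROUND_MIXTURE = ((0.1, 0.9), (0.05, 0.05), (0.5, 0.5))


@dataclass(frozen=True)
class ProjectSpec:
    """One synthetic project: sample count plus metadata value pools.

    ``metadata_keys`` maps a key to a pool of values sampled uniformly;
    ``fixed_metadata`` maps a key to an explicit per-sample value list (length
    ``n_samples``) for exact compositions.
    """

    name: str
    n_samples: int
    metadata_keys: dict = field(default_factory=dict)
    fixed_metadata: dict = field(default_factory=dict)

    def has_key(self, key: str) -> bool:
        return key == "project" or key in self.metadata_keys or key in self.fixed_metadata


@dataclass(frozen=True)
class PlantedEffect:
    """Group-dependent methylation planted over a genomic window.

    ``levels`` maps a value of ``group_key`` to (mean_beta, sd); samples whose
    value is not listed fall back to the background distribution.
    """

    chromosome: str
    start: int
    end: int
    group_key: str
    levels: dict  # value -> (mean, sd)
    gene: str | None = None


@dataclass(frozen=True)
class SimSpec:
    seed: int
    n_probes: int
    chromosomes: tuple = ("chr1",)
    island_fraction: float = 0.3
    snp_fraction: float = 0.05
    projects: tuple = ()
    effects: tuple = ()
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for name, value in (
            ("island_fraction", self.island_fraction),
            ("snp_fraction", self.snp_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {value}")
        for effect in self.effects:
            for value, (mean, sd) in effect.levels.items():
                if not 0.0 <= mean <= 1.0:
                    raise SimulationError(
                        f"planted mean {mean} for {effect.group_key}={value!r} outside [0, 1]"
                    )
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        object.__setattr__(self, "projects", tuple(self.projects))
        object.__setattr__(self, "effects", tuple(self.effects))


@dataclass
class Fixture:
    """In-memory simulation output; ``write`` lays it down as importable files."""

    annotation: list  # list[ProbeAnnotation]
    samples: list  # list[SampleRecord]
    betas: dict  # project -> BetaMatrix
    genes: list = field(default_factory=list)  # list[GeneModel]

    def write(self, out_dir: str) -> dict:
        """Write annotation CSV, sample JSON-lines, per-project beta CSV +
        GenomeStudio-style TSV, and a BED12 gene track. Deterministic bytes."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {}

        def _write(name, writer):
            path = os.path.join(out_dir, name)
            buf = io.StringIO()
            writer(buf)
            with open(path, "w", encoding="utf-8", newline="") as fh:
                fh.write(buf.getvalue())
            return path

        paths["annotation"] = _write(
            "annotation.csv", lambda fh: write_annotation_csv(self.annotation, fh)
        )
        paths["samples"] = _write(
            "samples.jsonl", lambda fh: write_sample_json(self.samples, fh)
        )
        for project, matrix in sorted(self.betas.items()):
            paths[f"betas:{project}"] = _write(
                f"betas_{project}.csv", lambda fh, m=matrix: write_beta_csv(m, fh)
            )
            paths[f"genomestudio:{project}"] = _write(
                f"genomestudio_{project}.txt",
                lambda fh, m=matrix, p=project: write_genomestudio(m, fh, project=p),
            )
        paths["genes"] = _write("genes.bed", lambda fh: write_gene_bed(self.genes, fh))
        return paths

    def load_into(self, store) -> None:
        from .importers import deposit_matrix

        store.load_annotation(self.annotation)
        projects = sorted({s.project for s in self.samples})
        for project in projects:
            store.register_samples(
                project, [s for s in self.samples if s.project == project]
            )
        for project, matrix in sorted(self.betas.items()):
            deposit_matrix(store, project, matrix)


def write_genomestudio(matrix: BetaMatrix, stream, project: str = "project") -> None:
    """Emit a GenomeStudio-style final report (with preamble) for a matrix."""
    stream.write("[Header]\n")
    stream.write("GSGX Version\t1.9.0\n")
    stream.write(f"Report\t{project} final report\n")
    stream.write("[Sample Methylation Profile]\n")
    cols = ["TargetID"]
    for sid in matrix.sample_ids:
        cols += [f"{sid}.AVG_Beta", f"{sid}.Detection Pval"]
    stream.write("\t".join(cols) + "\n")
    for probe_id, row in matrix.values.iterrows():
        fields = [probe_id]
        for value in row:
            if value != value:  # NaN
                fields += ["", ""]
            else:
                fields += [repr(float(value)), "0.0"]
        stream.write("\t".join(fields) + "\n")


def write_gene_bed(genes, stream) -> None:
    """Serialize gene models as BED12 (0-based half-open)."""
    for gene in genes:
        sizes = ",".join(str(e - s + 1) for s, e in gene.exons)
        starts = ",".join(str(s - gene.start) for s, _ in gene.exons)
        strand = gene.strand if gene.strand in ("+", "-") else "+"
        stream.write(
            "\t".join(
                [
                    gene.chromosome,
                    str(gene.start - 1),
                    str(gene.end),
                    gene.name,
                    "0",
                    strand,
                    str(gene.start - 1),
                    str(gene.end),
                    "0",
                    str(len(gene.exons)),
                    sizes + ",",
                    starts + ",",
                ]
            )
            + "\n"
        )


# ------------------------------------------------------------------ simulate


def simulate(spec: SimSpec) -> Fixture:
    """Generate a fixture from a :class:`SimSpec`; deterministic per seed."""
    _validate_effects(spec)
    rng = np.random.default_rng(spec.seed)
    annotation = _random_annotation(rng, spec)
    samples = _make_samples(rng, spec.projects)
    effect_of = _effect_index(annotation, spec.effects)
    betas = {}
    for project in spec.projects:
        members = [s for s in samples if s.project == project.name]
        betas[project.name] = _draw_betas(
            rng, annotation, members, effect_of, spec.noise_sd
        )
    genes = _effect_gene_models(spec.effects)
    return Fixture(annotation=annotation, samples=samples, betas=betas, genes=genes)


def _validate_effects(spec: SimSpec) -> None:
    for effect in spec.effects:
        for project in spec.projects:
            if not project.has_key(effect.group_key):
                raise SimulationError(
                    f"effect on {effect.chromosome}:{effect.start}-{effect.end} "
                    f"references key {effect.group_key!r} unknown to project "
                    f"{project.name!r}"
                )


def _random_annotation(rng: np.random.Generator, spec: SimSpec) -> list:
    per_chrom = np.full(len(spec.chromosomes), spec.n_probes // len(spec.chromosomes))
    per_chrom[: spec.n_probes % len(spec.chromosomes)] += 1
    records = []
    counter = 1
    for chrom, count in zip(spec.chromosomes, per_chrom):
        positions = np.cumsum(rng.integers(50, 2000, size=count))
        island_draw = rng.random(count)
        snp_in = rng.random(count) < spec.snp_fraction
        snp_at = rng.random(count) < spec.snp_fraction / 2
        unreliable = rng.random(count) < spec.snp_fraction / 2
        strands = rng.choice(["+", "-"], size=count)
        for i in range(count):
            if island_draw[i] < spec.island_fraction / 2:
                island = "high_density"
            elif island_draw[i] < spec.island_fraction:
                island = "intermediate_density"
            else:
                island = "none"
            position = int(positions[i])
            genes = tuple(
                e.gene
                for e in spec.effects
                if e.gene and e.chromosome == chrom and e.start <= position <= e.end
            )
            records.append(
                ProbeAnnotation(
                    probe_id=f"cg{counter:08d}",
                    chromosome=chrom,
                    position=position,
                    strand=str(strands[i]),
                    genes=genes,
                    island_class=island,
                    snp_in_probe=bool(snp_in[i]),
                    snp_at_cpg=bool(snp_at[i]),
                    reliable=not bool(unreliable[i]),
                )
            )
            counter += 1
    return records


def _make_samples(rng: np.random.Generator, projects) -> list:
    samples = []
    for project in projects:
        for key, values in project.fixed_metadata.items():
            if len(values) != project.n_samples:
                raise SimulationError(
                    f"fixed_metadata[{key!r}] for project {project.name!r} has "
                    f"{len(values)} values, expected {project.n_samples}"
                )
        for i in range(project.n_samples):
            metadata = {}
            for key in sorted(project.metadata_keys):
                pool = list(project.metadata_keys[key])
                metadata[key] = pool[int(rng.integers(len(pool)))]
            for key in sorted(project.fixed_metadata):
                metadata[key] = project.fixed_metadata[key][i]
            samples.append(
                SampleRecord(
                    sample_id=f"{project.name}-s{i + 1:03d}",
                    project=project.name,
                    metadata=metadata,
                )
            )
    return samples


def _effect_index(annotation, effects) -> dict:
    index = {}
    for ann in annotation:
        for effect in effects:
            if (
                effect.chromosome == ann.chromosome
                and effect.start <= ann.position <= effect.end
            ):
                index[ann.probe_id] = effect
                break
    return index


def _draw_betas(
    rng: np.random.Generator, annotation, samples, effect_of: dict, noise_sd: float
) -> BetaMatrix:
    means, sds, weights = BACKGROUND_MIXTURE
    sample_ids = [s.sample_id for s in samples]
    grid = np.empty((len(annotation), len(samples)))
    for i, ann in enumerate(annotation):
        component = int(rng.random() >= weights[0])
        base_mean, base_sd = means[component], max(sds[component], noise_sd)
        effect = effect_of.get(ann.probe_id)
        for j, sample in enumerate(samples):
            mean, sd = base_mean, base_sd
            if effect is not None:
                value = sample.get_value(effect.group_key)
                if value in effect.levels:
                    mean, sd = effect.levels[value]
            grid[i, j] = rng.normal(mean, sd)
    np.clip(grid, 0.0, 1.0, out=grid)
    values = pd.DataFrame(grid, index=[a.probe_id for a in annotation], columns=sample_ids)
    return BetaMatrix(values)


def _effect_gene_models(effects) -> list:
    genes = []
    seen = set()
    for effect in effects:
        if not effect.gene or effect.gene in seen:
            continue
        seen.add(effect.gene)
        span = effect.end - effect.start
        third = max(1, span // 3)
        exons = [
            (effect.start, effect.start + third // 2),
            (effect.start + third + 1, effect.start + third + third // 2),
            (effect.end - third // 2, effect.end),
        ]
        genes.append(
            GeneModel(
                name=effect.gene,
                chromosome=effect.chromosome,
                start=effect.start,
                end=effect.end,
                strand="+",
                exons=exons,
            )
        )
    return genes


# --------------------------------------------------- X-inactivation fixture

XCI_PROJECT = "xci_demo"
XCI_N_FEMALE = 22
XCI_N_MALE = 24

# Planted means mirror the qualitative sex-specific island patterns:
# an XIST-like locus (island: F ~0.5, M ~0.85), a MAOA-like locus subject to
# inactivation (island: F ~0.5, M low) and an RPS4X-like escapee (island low
# in both sexes, flanks high), with two SNP-at-CpG flank probes that fake a
# sex difference.
_XCI_LOCI = (
    {
        "gene": "XISTL",
        "flank_positions": (200, 400, 2400, 2600),
        "island_positions": ((1000, 1100, 1200, 1300), (1600, 1700, 1800, 1900)),
        "island_effect": {"female": (0.5, 0.05), "male": (0.85, 0.05)},
        "flank_effect": {"female": (0.8, 0.05), "male": (0.8, 0.05)},
        "span": (150, 2700),
    },
    {
        "gene": "MAOAL",
        "flank_positions": (4400, 4600, 5800, 6000),
        "island_positions": ((5000, 5100, 5200, 5300),),
        "island_effect": {"female": (0.5, 0.05), "male": (0.05, 0.03)},
        "flank_effect": {"female": (0.75, 0.05), "male": (0.75, 0.05)},
        "span": (4350, 6050),
    },
    {
        "gene": "RPS4XL",
        "flank_positions": (8400, 8600, 9700, 9900),
        "island_positions": ((9000, 9100, 9200, 9300),),
        "island_effect": {"female": (0.1, 0.03), "male": (0.1, 0.03)},
        "flank_effect": {"female": (0.85, 0.05), "male": (0.85, 0.05)},
        "span": (8350, 9950),
        "snp_positions": (8600, 9700),
        "snp_effect": {"female": (0.65, 0.05), "male": (0.9, 0.04)},
    },
)


def make_x_inactivation_fixture(seed: int) -> Fixture:
    """A 46-sample blood project (22 female / 24 male) with three X-linked
    loci planted to the canonical inactivation patterns, plus two
    SNP-confounded flank probes."""
    rng = np.random.default_rng(seed)
    annotation = []
    effects = []
    counter = 1

    def add_probe(position, island, gene, snp_at_cpg=False):
        nonlocal counter
        annotation.append(
            ProbeAnnotation(
                probe_id=f"cgX{counter:06d}",
                chromosome="chrX",
                position=position,
                strand="+",
                genes=(gene,),
                island_class=island,
                snp_in_probe=False,
                snp_at_cpg=snp_at_cpg,
                reliable=not snp_at_cpg,
            )
        )
        counter += 1

    for locus in _XCI_LOCI:
        snp_positions = set(locus.get("snp_positions", ()))
        for block in locus["island_positions"]:
            for position in block:
                add_probe(position, "high_density", locus["gene"])
                effects.append(
                    PlantedEffect(
                        chromosome="chrX",
                        start=position,
                        end=position,
                        group_key="sex",
                        levels=locus["island_effect"],
                        gene=locus["gene"],
                    )
                )
        for position in locus["flank_positions"]:
            snp = position in snp_positions
            add_probe(position, "none", locus["gene"], snp_at_cpg=snp)
            levels = locus["snp_effect"] if snp else locus["flank_effect"]
            effects.append(
                PlantedEffect(
                    chromosome="chrX",
                    start=position,
                    end=position,
                    group_key="sex",
                    levels=levels,
                    gene=locus["gene"],
                )
            )
    annotation.sort(key=lambda a: a.position)

    sexes = ["female"] * XCI_N_FEMALE + ["male"] * XCI_N_MALE
    order = rng.permutation(len(sexes))
    samples = [
        SampleRecord(
            sample_id=f"{XCI_PROJECT}-s{i + 1:03d}",
            project=XCI_PROJECT,
            metadata={"sex": sexes[order[i]], "tissuetype": "blood"},
        )
        for i in range(len(sexes))
    ]

    effect_of = _effect_index(annotation, effects)
    betas = {XCI_PROJECT: _draw_betas(rng, annotation, samples, effect_of, 0.05)}
    genes = [
        GeneModel(
            name=locus["gene"],
            chromosome="chrX",
            start=locus["span"][0],
            end=locus["span"][1],
            strand="+",
            exons=[
                (block[0], block[-1]) for block in locus["island_positions"]
            ]
            or [(locus["span"][0], locus["span"][1])],
        )
        for locus in _XCI_LOCI
    ]
    return Fixture(annotation=annotation, samples=samples, betas=betas, genes=genes)


# ------------------------------------------------------- full-array manifest


def make_full_array_manifest(seed: int) -> pd.DataFrame:
    """A synthetic annotation table with the full array's probe count
    (485,577 rows, unique ids, valid positions), as a DataFrame matching the
    annotation CSV column layout."""
    rng = np.random.default_rng(seed)
    n = FULL_ARRAY_PROBE_COUNT
    chromosomes = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
    per_chrom = np.full(len(chromosomes), n // len(chromosomes))
    per_chrom[: n % len(chromosomes)] += 1
    chrom_col = np.repeat(chromosomes, per_chrom)
    positions = np.concatenate(
        [np.cumsum(rng.integers(50, 1000, size=count)) for count in per_chrom]
    )
    island_draw = rng.random(n)
    island = np.where(
        island_draw < 0.15,
        "high_density",
        np.where(island_draw < 0.3, "intermediate_density", "none"),
    )
    snp_in = rng.random(n) < 0.05
    snp_at = rng.random(n) < 0.02
    reliable = rng.random(n) >= 0.01
    has_gene = rng.random(n) < 0.4
    gene_ids = np.where(
        has_gene,
        np.char.add("G", (positions // 100_000).astype(str)),
        "",
    )
    genes = np.where(
        has_gene, np.char.add(np.char.add(chrom_col.astype(str), "_"), gene_ids), ""
    )
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(1, n + 1)],
            "chromosome": chrom_col,
            "position": positions.astype(np.int64),
            "strand": rng.choice(["+", "-"], size=n),
            "genes": genes,
            "island_class": island,
            "snp_in_probe": np.where(snp_in, "true", "false"),
            "snp_at_cpg": np.where(snp_at, "true", "false"),
            "reliable": np.where(reliable, "true", "false"),
        }
    )


def write_manifest_csv(manifest: pd.DataFrame, path: str) -> None:
    manifest.to_csv(path, index=False)


def manifest_records(manifest: pd.DataFrame):
    """Stream :class:`ProbeAnnotation` records from a manifest DataFrame."""
    for row in manifest.itertuples(index=False):
        yield ProbeAnnotation(
            probe_id=row.probe_id,
            chromosome=row.chromosome,
            position=int(row.position),
            strand=row.strand,
            genes=tuple(g for g in str(row.genes).split(";") if g),
            island_class=row.island_class,
            snp_in_probe=row.snp_in_probe == "true",
            snp_at_cpg=row.snp_at_cpg == "true",
            reliable=row.reliable == "true",
        )
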