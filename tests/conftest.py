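import json

import pytest

from betascope import (
    GenomicRegion,
    GroupSpec,
    ProbeAnnotation,
    SampleRecord,
    group_samples,
    make_x_inactivation_fixture,
    open_store,
)


def make_probes(positions, chromosome="chr1", **overrides):
    """One annotation record per position, ids p0001, p0002, ..."""
    records = []
    for i, pos in enumerate(positions, 1):
        kwargs = dict(
            probe_id=f"p{i:04d}",
            chromosome=chromosome,
            position=pos,
        )
        kwargs.update({k: v[i - 1] if isinstance(v, (list, tuple)) else v
                       for k, v in overrides.items()})
        records.append(ProbeAnnotation(**kwargs))
    return records


def make_samples(project, n, **metadata_lists):
    """n samples named <project>-s1..; metadata_lists maps key -> per-sample
    values, with None meaning the key is omitted for that sample."""
    records = []
    for i in range(n):
        metadata = {}
        for key, values in metadata_lists.items():
            value = values[i] if isinstance(values, (list, tuple)) else values
            if value is not None:
                metadata[key] = value
        records.append(SampleRecord(f"{project}-s{i + 1}", project, metadata))
    return records


@pytest.fixture
def mem_store():
    return open_store(backend="memory")


@pytest.fixture
def loaded_store(mem_store):
    """Three probes on chr1 at 100/200/300, one project, three samples with
    a deposited beta per (probe, sample)."""
    mem_store.load_annotation(make_probes([100, 200, 300]))
    mem_store.register_samples("p1", make_samples("p1", 3, sex=["F", "M", "F"]))
    for j, sid in enumerate(["p1-s1", "p1-s2", "p1-s3"]):
        mem_store.deposit_betas(
            "p1", sid, {f"p{i:04d}": round(0.1 * (i + j), 3) for i in (1, 2, 3)}
        )
    return mem_store


@pytest.fixture(scope="session")
def xci_fixture():
    return make_x_inactivation_fixture(seed=7)


@pytest.fixture
def xci_store(xci_fixture):
    store = open_store(backend="memory")
    xci_fixture.load_into(store)
    return store


def region_dataset(store, chromosome, start, end, projects):
    return store.query_region(GenomicRegion(chromosome, start, end), projects)


def groups_by(samples, *keys):
    return group_samples(samples, GroupSpec(mode="within_project", keys=tuple(keys)))


def dump_docs(store):
    return [json.loads(line) for line in store.dump()]
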