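"""Partition samples into display groups.

Within a project samples may be stratified by up to three metadata keys
simultaneously; across projects only the reserved keys ("project",
"tissuetype") are allowed. Samples missing any grouping key are excluded,
never given a placeholder group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import GroupSpecError
from .types import SampleRecord

MAX_GROUP_KEYS = 3
CROSS_PROJECT_KEYS = ("project", "tissuetype")

LABEL_SEPARATOR = " / "


@dataclass(frozen=True)
class GroupSpec:
    """How to partition samples: mode plus the grouping key(s)."""

    mode: str  # "within_project" | "cross_project"
    keys: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "keys", tuple(self.keys))
        if self.mode not in ("within_project", "cross_project"):
            raise GroupSpecError(
                f"mode must be 'within_project' or 'cross_project', got {self.mode!r}"
            )
        if self.mode == "within_project":
            if len(self.keys) == 0:
                raise GroupSpecError("at least one grouping key is required")
            if len(self.keys) > MAX_GROUP_KEYS:
                raise GroupSpecError(
                    f"samples may be grouped by at most {MAX_GROUP_KEYS} keys within "
                    f"a project; got {len(self.keys)}"
                )
        else:
            if len(self.keys) != 1 or self.keys[0] not in CROSS_PROJECT_KEYS:
                raise GroupSpecError(
                    "cross-project grouping requires exactly one of the reserved "
                    f"keys {CROSS_PROJECT_KEYS}; got {self.keys!r}"
                )


@dataclass
class GroupAssignment:
    """Result of grouping: label tuple -> member sample_ids, plus the samples
    excluded for lacking a grouping key. Groups are ordered by sorted label."""

    keys: tuple[str, ...]
    groups: dict = field(default_factory=dict)  # tuple -> list[str]
    excluded: list = field(default_factory=list)  # list[str]

    @property
    def labels(self) -> list[tuple]:
        return list(self.groups)

    def label_text(self, label: tuple) -> str:
        return LABEL_SEPARATOR.join(str(v) for v in label)

    def group_of(self) -> dict:
        """sample_id -> label map over all grouped samples."""
        return {sid: label for label, members in self.groups.items() for sid in members}

    def n_samples(self) -> int:
        return sum(len(m) for m in self.groups.values()) + len(self.excluded)


def _label_sort_key(label: tuple) -> tuple:
    # mixed scalar types are not mutually orderable; sort on (type, str) pairs
    return tuple((type(v).__name__, str(v)) for v in label)


def group_samples(samples: list[SampleRecord], spec: GroupSpec) -> GroupAssignment:
    """Assign each sample possessing all of ``spec.keys`` to the group labeled
    by its value tuple; samples missing any key are excluded. Deterministic:
    group labels are sorted, members keep input order."""
    groups: dict[tuple, list[str]] = {}
    excluded: list[str] = []
    for sample in samples:
        values = [sample.get_value(k) for k in spec.keys]
        if any(v is None for v in values):
            excluded.append(sample.sample_id)
            continue
        groups.setdefault(tuple(values), []).append(sample.sample_id)
    ordered = {label: groups[label] for label in sorted(groups, key=_label_sort_key)}
    return GroupAssignment(keys=spec.keys, groups=ordered, excluded=excluded)


def cross_project_groups(store, projects: list[str], key: str) -> GroupAssignment:
    """Group the union of the projects' samples by one reserved key."""
    spec = GroupSpec(mode="cross_project", keys=(key,))
    samples: list[SampleRecord] = []
    for project in sorted(set(projects)):
        samples.extend(store.samples(project))
    return group_samples(samples, spec)
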