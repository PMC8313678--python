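"""Cohort design: experimental groups, sample ids and patient pairing.

The default design mirrors a sepsis case/control cohort with repeated
sampling: six healthy controls, nine patients sampled in the acute phase
(Sepsis) and the same nine patients sampled again before ICU discharge
(Recovery), so Sepsis and Recovery samples are paired one-to-one.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class StudyDesign:
    """Ordered group -> sample-id assignment with optional pairing.

    Parameters
    ----------
    samples
        Mapping from group name to the tuple of sample ids in that group.
        Insertion order defines the group order used everywhere downstream.
    pairing
        Map from a sample of ``paired_groups[0]`` to its partner sample in
        ``paired_groups[1]``. Must be a bijection between the two groups.
    paired_groups
        The pair of group names linked by ``pairing`` (None if unpaired).
    """

    samples: dict[str, tuple[str, ...]]
    pairing: dict[str, str] = field(default_factory=dict)
    paired_groups: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        all_ids = [s for grp in self.samples.values() for s in grp]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("sample ids must be globally unique")
        for g, ids in self.samples.items():
            if len(ids) == 0:
                raise ValueError(f"group {g!r} has no samples")
        if self.pairing:
            if self.paired_groups is None:
                raise ValueError("pairing given without paired_groups")
            a, b = self.paired_groups
            if a not in self.samples or b not in self.samples:
                raise ValueError(f"paired groups {a!r}/{b!r} not in design")
            keys, vals = set(self.pairing), set(self.pairing.values())
            if keys != set(self.samples[a]) or vals != set(self.samples[b]):
                raise ValueError("pairing must be a bijection between the paired groups")
            if len(vals) != len(self.pairing):
                raise ValueError("pairing maps two samples to the same partner")

    # -- accessors ---------------------------------------------------------
    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(self.samples)

    @property
    def all_samples(self) -> tuple[str, ...]:
        return tuple(s for grp in self.samples.values() for s in grp)

    def samples_of(self, group: str) -> tuple[str, ...]:
        try:
            return self.samples[group]
        except KeyError:
            raise KeyError(f"unknown group {group!r}") from None

    def group_of(self, sample: str) -> str:
        for g, ids in self.samples.items():
            if sample in ids:
                return g
        raise KeyError(f"unknown sample {sample!r}")

    # -- construction ------------------------------------------------------
    @classmethod
    def default(cls) -> "StudyDesign":
        """Three-group sepsis cohort: Control n=6, Sepsis n=9, Recovery n=9,
        with Sepsis patient i paired to Recovery patient i."""
        sepsis = tuple(f"S{i}" for i in range(1, 10))
        recovery = tuple(f"R{i}" for i in range(1, 10))
        return cls(
            samples={
                "Control": tuple(f"C{i}" for i in range(1, 7)),
                "Sepsis": sepsis,
                "Recovery": recovery,
            },
            pairing=dict(zip(sepsis, recovery)),
            paired_groups=("Sepsis", "Recovery"),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StudyDesign":
        """Build from a table with columns sample_id, group, pair_id.

        ``pair_id`` links the two samples of one subject across the two
        paired groups; it may be empty/NaN throughout for unpaired designs.
        """
        samples: dict[str, list[str]] = {}
        for _, row in frame.iterrows():
            samples.setdefault(str(row["group"]), []).append(str(row["sample_id"]))
        pairing: dict[str, str] = {}
        paired_groups = None
        if "pair_id" in frame.columns:
            tagged = frame.dropna(subset=["pair_id"])
            tagged = tagged[tagged["pair_id"].astype(str).str.len() > 0]
            if len(tagged):
                groups = list(dict.fromkeys(tagged["group"]))
                if len(groups) != 2:
                    raise ValueError("pair_id must span exactly two groups")
                paired_groups = (groups[0], groups[1])
                by_pair = tagged.groupby("pair_id")
                for pid, sub in by_pair:
                    if len(sub) != 2:
                        raise ValueError(f"pair_id {pid!r} does not link exactly two samples")
                    d = dict(zip(sub["group"], sub["sample_id"]))
                    pairing[str(d[groups[0]])] = str(d[groups[1]])
        return cls(
            samples={g: tuple(ids) for g, ids in samples.items()},
            pairing=pairing,
            paired_groups=paired_groups,
        )

    def to_frame(self) -> pd.DataFrame:
        pair_of: dict[str, str] = {}
        if self.pairing:
            for i, (a, b) in enumerate(sorted(self.pairing.items()), start=1):
                pair_of[a] = pair_of[b] = f"pair{i}"
        rows = [
            {"sample_id": s, "group": g, "pair_id": pair_of.get(s, "")}
            for g, ids in self.samples.items()
            for s in ids
        ]
        return pd.DataFrame(rows, columns=["sample_id", "group", "pair_id"])


def read_design(path) -> StudyDesign:
    return StudyDesign.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_design(design: StudyDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)
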