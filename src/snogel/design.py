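"""Experiment design: groups, replicates, gel inventory and cognate pairing.

A multiplexed ascorbate-switch 2DE experiment runs every biological sample on
two gels: an ascorbate-treated aliquot (``ASC_PLUS``, BODIPY reports total
reduced cysteine and hence abundance) and a neocuproine-stabilised aliquot
(``ASC_MINUS``, BODIPY reports only the non-nitrosylated fraction).  All
per-gel normalisation factors derive from the sample's cognate ``ASC_PLUS``
gel, so the design must record that pairing explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import yaml

__all__ = [
    "Aliquot",
    "GelRecord",
    "ExperimentDesign",
    "DesignError",
]


class DesignError(ValueError):
    """Raised when an experiment design violates its structural invariants."""


class Aliquot(str, Enum):
    """Ascorbate treatment state of the aliquot run on a gel."""

    ASC_PLUS = "ASC_PLUS"
    ASC_MINUS = "ASC_MINUS"


@dataclass(frozen=True)
class GelRecord:
    """One physical 2D gel: which sample, group and aliquot it carries."""

    gel_id: str
    sample_id: str
    group: str
    aliquot: Aliquot


@dataclass(frozen=True)
class ExperimentDesign:
    """Groups, replicates and the gel inventory of one experiment.

    Parameters
    ----------
    group_labels
        Ordered group names; the first is the control group.
    n_replicates_per_group
        Number of biological replicates (samples) per group.
    gels
        One :class:`GelRecord` per physical gel.  Every sample must appear on
        exactly one ``ASC_PLUS`` and one ``ASC_MINUS`` gel.
    reference_gel_id
        The ``ASC_PLUS`` control-group gel whose total spot volume anchors
        the bias-factor normalisation.
    """

    group_labels: tuple[str, ...]
    n_replicates_per_group: int
    gels: tuple[GelRecord, ...]
    reference_gel_id: str

    def __post_init__(self) -> None:
        if len(self.group_labels) < 1:
            raise DesignError("at least one group is required")
        if len(set(self.group_labels)) != len(self.group_labels):
            raise DesignError("group labels must be unique")
        if self.n_replicates_per_group < 1:
            raise DesignError("n_replicates_per_group must be positive")

        gel_ids = [g.gel_id for g in self.gels]
        if len(set(gel_ids)) != len(gel_ids):
            raise DesignError("gel_ids must be unique")

        # every sample: exactly one gel per aliquot, consistent group
        per_sample: dict[str, dict[Aliquot, GelRecord]] = {}
        for g in self.gels:
            if g.group not in self.group_labels:
                raise DesignError(f"gel {g.gel_id!r} has unknown group {g.group!r}")
            slot = per_sample.setdefault(g.sample_id, {})
            if g.aliquot in slot:
                raise DesignError(
                    f"sample {g.sample_id!r} has more than one {g.aliquot.value} gel"
                )
            slot[g.aliquot] = g
        for sid, slot in per_sample.items():
            if set(slot) != {Aliquot.ASC_PLUS, Aliquot.ASC_MINUS}:
                raise DesignError(
                    f"sample {sid!r} lacks a cognate ASC_PLUS/ASC_MINUS gel pair"
                )
            if slot[Aliquot.ASC_PLUS].group != slot[Aliquot.ASC_MINUS].group:
                raise DesignError(f"sample {sid!r} gels disagree on group")

        for label in self.group_labels:
            n = len({g.sample_id for g in self.gels if g.group == label})
            if n != self.n_replicates_per_group:
                raise DesignError(
                    f"group {label!r} has {n} samples, "
                    f"expected {self.n_replicates_per_group}"
                )

        ref = self.gel(self.reference_gel_id)
        if ref is None:
            raise DesignError(f"reference gel {self.reference_gel_id!r} not found")
        if ref.aliquot is not Aliquot.ASC_PLUS:
            raise DesignError("reference gel must be an ASC_PLUS gel")
        if ref.group != self.control_group:
            raise DesignError("reference gel must belong to the control group")

    # ------------------------------------------------------------------ #
    @property
    def control_group(self) -> str:
        return self.group_labels[0]

    @property
    def treatment_groups(self) -> tuple[str, ...]:
        return self.group_labels[1:]

    def gel(self, gel_id: str) -> GelRecord | None:
        for g in self.gels:
            if g.gel_id == gel_id:
                return g
        return None

    def samples(self, group: str | None = None) -> list[str]:
        """Sample ids in gel order, optionally restricted to one group."""
        seen: list[str] = []
        for g in self.gels:
            if group is not None and g.group != group:
                continue
            if g.sample_id not in seen:
                seen.append(g.sample_id)
        return seen

    def sample_group(self, sample_id: str) -> str:
        for g in self.gels:
            if g.sample_id == sample_id:
                return g.group
        raise DesignError(f"unknown sample {sample_id!r}")

    def gel_for(self, sample_id: str, aliquot: Aliquot) -> GelRecord:
        for g in self.gels:
            if g.sample_id == sample_id and g.aliquot is aliquot:
                return g
        raise DesignError(f"no {aliquot.value} gel for sample {sample_id!r}")

    def gels_for(self, aliquot: Aliquot) -> list[GelRecord]:
        return [g for g in self.gels if g.aliquot is aliquot]

    def cognate_asc_plus(self, gel_id: str) -> GelRecord:
        """The same sample's ASC_PLUS gel (the normalisation donor)."""
        g = self.gel(gel_id)
        if g is None:
            raise DesignError(f"unknown gel {gel_id!r}")
        return self.gel_for(g.sample_id, Aliquot.ASC_PLUS)

    def comparisons(self) -> list[tuple[str, str]]:
        """All (experimental, control) group pairs, later vs earlier.

        For groups ``(M0, M1, M2)`` this yields ``(M1, M0)``, ``(M2, M0)``
        and ``(M2, M1)`` — each treatment against the control plus the
        treatment-vs-treatment contrast.
        """
        out = []
        labels = self.group_labels
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                out.append((labels[j], labels[i]))
        return out

    # ------------------------------------------------------------------ #
    @classmethod
    def balanced(
        cls,
        group_labels: tuple[str, ...] = ("M0", "M1", "M2"),
        n_replicates: int = 4,
    ) -> "ExperimentDesign":
        """A balanced design: every group gets ``n_replicates`` samples, each
        with a cognate ASC_PLUS/ASC_MINUS gel pair (the default reproduces a
        3-group x 4-replicate x 2-aliquot, 24-gel layout)."""
        gels = []
        for label in group_labels:
            for r in range(1, n_replicates + 1):
                sid = f"{label}_r{r}"
                gels.append(GelRecord(f"{sid}_plus", sid, label, Aliquot.ASC_PLUS))
                gels.append(GelRecord(f"{sid}_minus", sid, label, Aliquot.ASC_MINUS))
        return cls(
            group_labels=tuple(group_labels),
            n_replicates_per_group=n_replicates,
            gels=tuple(gels),
            reference_gel_id=f"{group_labels[0]}_r1_plus",
        )

    # -- serialisation -------------------------------------------------- #
    def to_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "n_replicates_per_group": self.n_replicates_per_group,
            "reference_gel_id": self.reference_gel_id,
            "gels": [
                {
                    "gel_id": g.gel_id,
                    "sample_id": g.sample_id,
                    "group": g.group,
                    "aliquot": g.aliquot.value,
                }
                for g in self.gels
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return cls(
            group_labels=tuple(d["group_labels"]),
            n_replicates_per_group=int(d["n_replicates_per_group"]),
            gels=tuple(
                GelRecord(
                    g["gel_id"], g["sample_id"], g["group"], Aliquot(g["aliquot"])
                )
                for g in d["gels"]
            ),
            reference_gel_id=d["reference_gel_id"],
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentDesign":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)
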