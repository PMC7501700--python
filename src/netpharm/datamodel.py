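"""Core domain types for network pharmacology of multi-herb formulas.

The pipeline operates on five kinds of objects: compounds (with
physicochemical and ADMET annotations), herbs (sets of compound ids),
binary substructure fingerprints, drug-target interactions (DTIs), and
gene sets (disease genes or pathway/GO annotations).  All gene identity
is by uppercased symbol string; compound identity is the supplied id
string (typically a PubChem CID rendered as text).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "PhyschemProfile",
    "AdmetScores",
    "CompoundRecord",
    "HerbFormula",
    "GeneSet",
    "DTIRecord",
    "FingerprintTable",
    "PipelineConfig",
    "ValidationReport",
    "normalize_gene",
]


def normalize_gene(symbol: str) -> str:
    """Canonical gene identity: stripped, uppercased symbol (idempotent)."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class PhyschemProfile:
    """Physicochemical profile used by the Rule-of-Five gate.

    Any field may be ``None`` when the source table lacks the value; a
    compound with an incomplete profile is *ineligible* for drug-likeness
    screening rather than passed or failed.
    """

    mw: Optional[float] = None  # molecular weight, Da
    alogp: Optional[float] = None  # computed octanol-water partition estimate
    hbd: Optional[int] = None  # H-bond donor count
    hba: Optional[int] = None  # H-bond acceptor count

    def __post_init__(self) -> None:
        if self.mw is not None and not self.mw > 0:
            raise ValueError(f"molecular weight must be > 0, got {self.mw}")
        for name in ("hbd", "hba"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def complete(self) -> bool:
        return None not in (self.mw, self.alogp, self.hbd, self.hba)


@dataclass(frozen=True)
class AdmetScores:
    """Positive-class probabilities from an external ADMET classifier."""

    hia_prob: float  # human intestinal absorption
    bbb_prob: float  # blood-brain barrier penetration

    def __post_init__(self) -> None:
        for name in ("hia_prob", "bbb_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str
    smiles: Optional[str] = None
    physchem: Optional[PhyschemProfile] = None
    admet: Optional[AdmetScores] = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")


@dataclass(frozen=True)
class HerbFormula:
    """One herb of a formula: a named set of member compounds.

    ``role_class`` encodes the Jun-Chen-Zuo-Shi (sovereign-minister-
    assistant-courier) compositional role where known.
    """

    herb_id: str
    name: str
    compound_ids: frozenset[str]
    role_class: Optional[str] = None  # "JunChen" | "ZuoShi"

    def __post_init__(self) -> None:
        if self.role_class not in (None, "JunChen", "ZuoShi"):
            raise ValueError(f"unknown role_class {self.role_class!r}")
        object.__setattr__(self, "compound_ids", frozenset(self.compound_ids))


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        genes = frozenset(normalize_gene(g) for g in self.genes if g.strip())
        if not genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)


KNOWN = "known"
PREDICTED = "predicted"


@dataclass(frozen=True)
class DTIRecord:
    """A drug-target interaction edge with provenance.

    ``score`` carries the diffusion score for predicted edges and is
    ``None`` for experimentally known ones.
    """

    compound_id: str
    target: str
    provenance: str = KNOWN
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.provenance not in (KNOWN, PREDICTED):
            raise ValueError(f"provenance must be known|predicted, got {self.provenance!r}")
        object.__setattr__(self, "target", normalize_gene(self.target))


class FingerprintTable:
    """Binary substructure-fingerprint matrix, compounds x bits.

    Rows follow ``compound_ids`` order; entries are strictly 0/1.
    """

    def __init__(
        self,
        compound_ids: Sequence[str],
        bit_names: Sequence[str],
        bits: np.ndarray,
    ) -> None:
        bits = np.asarray(bits)
        if bits.shape != (len(compound_ids), len(bit_names)):
            raise ValueError(
                f"bit matrix shape {bits.shape} does not match "
                f"{len(compound_ids)} compounds x {len(bit_names)} bits"
            )
        if bits.size and not np.isin(bits, (0, 1)).all():
            bad = bits[~np.isin(bits, (0, 1))][0]
            raise ValueError(f"fingerprint entries must be 0/1, found {bad!r}")
        if len(set(compound_ids)) != len(compound_ids):
            raise ValueError("duplicate compound ids in fingerprint table")
        self.compound_ids = list(compound_ids)
        self.bit_names = list(bit_names)
        self.bits = bits.astype(np.int8)
        self._index = {c: i for i, c in enumerate(self.compound_ids)}

    def row(self, compound_id: str) -> np.ndarray:
        return self.bits[self._index[compound_id]]

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._index

    def __len__(self) -> int:
        return len(self.compound_ids)

    def subset(self, compound_ids: Iterable[str]) -> "FingerprintTable":
        ids = list(compound_ids)
        rows = [self._index[c] for c in ids]
        return FingerprintTable(ids, self.bit_names, self.bits[rows])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FingerprintTable)
            and self.compound_ids == other.compound_ids
            and self.bit_names == other.bit_names
            and np.array_equal(self.bits, other.bits)
        )


@dataclass
class PipelineConfig:
    """Parameters of the full analysis, with the published defaults.

    Diffusion uses four parameters: alpha balances the initial resource
    between the substructure and known-target sides, beta weights the
    two edge types during spreading, gamma is the hub-degree exponent,
    and k is the number of diffusion rounds.
    """

    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = -0.5
    k: int = 2
    top_n: int = 20
    universe_policy: str = "network"  # "network" | "union"
    admet_threshold: float = 0.5
    q_star: float = 0.05
    seed: int = 0
    # input paths (optional; the library API passes objects directly)
    compounds_path: Optional[str] = None
    herbs_path: Optional[str] = None
    fingerprints_path: Optional[str] = None
    dti_path: Optional[str] = None
    disease_path: Optional[str] = None
    main_components_path: Optional[str] = None
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.k < 1 or int(self.k) != self.k:
            raise ValueError("k must be an integer >= 1")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.universe_policy not in ("network", "union"):
            raise ValueError(f"unknown universe policy {self.universe_policy!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ValidationReport:
    """Outcome of dataset cross-validation: nothing fatal, only findings."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    info: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = (
            [f"ERROR: {m}" for m in self.errors]
            + [f"WARNING: {m}" for m in self.warnings]
            + [f"INFO: {m}" for m in self.info]
        )
        return "\n".join(lines) if lines else "dataset consistent; no issues"
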