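"""Synthetic multi-herb formula datasets with controllable signal.

The generator emulates the statistical structure the analysis assumes:
several herbs drawing overlapping compound sets from a shared pool,
sparse binary substructure fingerprints, a sparse known drug-target
interaction network whose wiring is coupled to the fingerprints, a
disease gene subset of the target universe, and a planted subset of
active compounds whose target profiles are enriched for disease genes
at a controllable strength.

The fingerprint-target coupling follows a scaffold-class model, the
way chemical libraries actually behave: compounds belong to scaffold
classes, each class displays a set of signature substructure bits, and
each class preferentially binds one module of targets.  A target's
"driver bits" are the signature bits of its module's class; compounds
carrying them are preferentially wired to it.  This makes held-out
interactions recoverable both through shared substructures and through
co-targeting, which is exactly the structure resource diffusion
exploits.

``null_dataset`` produces the matching no-signal control: no planted
actives and no fingerprint-target coupling (targets wired uniformly at
random), for type-I-error and AUC~0.5 checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    AdmetScores,
    CompoundRecord,
    DTIRecord,
    FingerprintTable,
    GeneSet,
    HerbFormula,
    PhyschemProfile,
)
from . import io as npio

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "null_dataset", "holdout_split"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults give six herbs over a 400-compound pool, 200 targets, 300
    fingerprint bits, 30 disease genes and 20 planted active compounds.
    ``dti_density`` controls the expected fraction of targets a compound
    binds (0.06 -> ~12 known targets per compound); ``coupling`` is the
    extra sampling weight a target gains per shared driver bit, and
    ``planting_strength`` the minimum fraction of a planted compound's
    targets drawn from disease genes.
    """

    n_herbs: int = 6
    n_compounds: int = 400
    compounds_per_herb: int = 100
    herb_reuse_prob: float = 0.5
    n_targets: int = 200
    n_bits: int = 300
    bit_density: float = 0.02
    dti_density: float = 0.06
    n_scaffold_classes: int = 16
    signature_bits_per_class: int = 12
    signature_prob: float = 0.8
    coupling: float = 20.0
    n_disease_genes: int = 30
    n_planted: int = 20
    planting_strength: float = 0.6
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "herb_reuse_prob",
            "bit_density",
            "dti_density",
            "planting_strength",
            "signature_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_herbs", "n_compounds", "n_targets", "n_bits", "n_scaffold_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_scaffold_classes * self.signature_bits_per_class > self.n_bits:
            raise ValueError("signature bits exceed the fingerprint width")
        if self.n_disease_genes > self.n_targets:
            raise ValueError("more disease genes than targets")
        if self.n_planted > self.n_compounds:
            raise ValueError("more planted actives than compounds")
        if self.compounds_per_herb > self.n_compounds:
            raise ValueError("herb size exceeds compound pool")
        if self.n_planted > 0:
            background = self.n_disease_genes / self.n_targets
            if not self.planting_strength > background:
                raise ValueError(
                    "planting_strength must exceed the background disease fraction "
                    f"({background:.3f}) for planting to mean anything"
                )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    compounds: list[CompoundRecord]
    herbs: list[HerbFormula]
    fingerprints: FingerprintTable
    dtis: list[DTIRecord]
    disease: GeneSet
    planted: set[str]  # ground-truth active compound ids
    driver_bits: dict[str, tuple[str, ...]]  # target -> coupled bit names

    def write(self, out_dir) -> dict[str, Path]:
        """Emit the dataset in the pipeline's external file formats."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "compounds": out / "compounds.csv",
            "herbs": out / "herbs.tsv",
            "fingerprints": out / "fingerprints.csv",
            "dti": out / "dti.tsv",
            "disease": out / "disease.gmt",
            "truth": out / "truth.tsv",
        }
        npio.write_compound_table(self.compounds, paths["compounds"])
        npio.write_herb_table(self.herbs, paths["herbs"])
        npio.write_fingerprint_table(self.fingerprints, paths["fingerprints"])
        npio.write_dti_table(self.dtis, paths["dti"])
        npio.write_gene_sets_gmt([self.disease], paths["disease"])
        with open(paths["truth"], "w") as fh:
            fh.write("compound_id\tplanted\n")
            for c in self.compounds:
                fh.write(f"{c.compound_id}\t{int(c.compound_id in self.planted)}\n")
        return paths


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Independent per-component RNG streams derived from one seed.

    Each component gets its own child of the master SeedSequence, so
    adding a component never perturbs the draws of the others.
    """
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Build one fully reproducible synthetic formula dataset."""
    rng = _streams(
        config.seed,
        ["fingerprints", "drivers", "dtis", "planting", "herbs", "disease", "physchem"],
    )
    width = max(4, len(str(config.n_compounds)))
    compound_ids = [f"C{i:0{width}d}" for i in range(1, config.n_compounds + 1)]
    targets = [f"G{j:04d}" for j in range(1, config.n_targets + 1)]
    bit_names = [f"FP{b:04d}" for b in range(1, config.n_bits + 1)]

    # scaffold classes: each compound belongs to one class whose
    # signature bits occupy a dedicated block at the head of the
    # fingerprint; the remaining bits are background noise
    spc = config.signature_bits_per_class
    cls_rng = rng["drivers"]
    classes = cls_rng.integers(config.n_scaffold_classes, size=config.n_compounds)

    fp_rng = rng["fingerprints"]
    bits = fp_rng.random((config.n_compounds, config.n_bits)) < config.bit_density
    for i, cl in enumerate(classes):
        block = slice(cl * spc, (cl + 1) * spc)
        bits[i, block] |= fp_rng.random(spc) < config.signature_prob
    bits = bits.astype(np.int8)
    for i in np.flatnonzero(~bits.any(axis=1)):
        bits[i, fp_rng.integers(config.n_bits)] = 1
    fingerprints = FingerprintTable(compound_ids, bit_names, bits)

    # disease genes: a random subset of the target universe
    disease_genes = set(
        np.array(targets)[
            rng["disease"].choice(config.n_targets, config.n_disease_genes, replace=False)
        ]
    )
    disease = GeneSet("DISEASE", "synthetic disease gene set", frozenset(disease_genes))

    # coupling: targets fall round-robin into one module per scaffold
    # class; a target's driver bits are its class's signature bits, and
    # compounds carrying them are preferentially wired to it below
    target_class = np.arange(config.n_targets) % config.n_scaffold_classes
    driver_mat = np.zeros((config.n_bits, config.n_targets))
    for j in range(config.n_targets):
        driver_mat[target_class[j] * spc : (target_class[j] + 1) * spc, j] = 1.0
    driver_bits = {
        t: tuple(bit_names[b] for b in np.flatnonzero(driver_mat[:, j]))
        for j, t in enumerate(targets)
    }
    # sampling weight: 1 + coupling * (driver bits the compound carries)
    weights = 1.0 + config.coupling * (bits @ driver_mat)  # compounds x targets

    # planted actives drawn once; their DTIs are forced disease-heavy
    plant_rng = rng["planting"]
    planted = set(
        np.array(compound_ids)[
            plant_rng.choice(config.n_compounds, config.n_planted, replace=False)
        ]
    )
    disease_mask = np.array([t in disease_genes for t in targets])

    dti_rng = rng["dtis"]
    dtis: list[DTIRecord] = []
    tgt_arr = np.array(targets)
    for i, cid in enumerate(compound_ids):
        n_t = max(1, int(dti_rng.binomial(config.n_targets, config.dti_density)))
        w = weights[i].astype(float)
        if cid in planted:
            # at least ceil(s * n_t) targets from the disease subset
            n_dis = min(math.ceil(config.planting_strength * n_t), config.n_disease_genes)
            n_other = min(n_t - n_dis, config.n_targets - config.n_disease_genes)
            wd = w * disease_mask
            wo = w * ~disease_mask
            chosen = list(
                dti_rng.choice(tgt_arr, n_dis, replace=False, p=wd / wd.sum())
            )
            if n_other > 0:
                chosen += list(
                    dti_rng.choice(tgt_arr, n_other, replace=False, p=wo / wo.sum())
                )
        else:
            chosen = list(dti_rng.choice(tgt_arr, n_t, replace=False, p=w / w.sum()))
        dtis.extend(DTIRecord(cid, t) for t in sorted(chosen))

    # herbs: sequential sampling from the shared pool with reuse
    herb_rng = rng["herbs"]
    used: list[str] = []
    herbs: list[HerbFormula] = []
    unused = list(compound_ids)
    for h in range(config.n_herbs):
        members: set[str] = set()
        while len(members) < config.compounds_per_herb:
            pool_used = [c for c in used if c not in members]
            if pool_used and herb_rng.random() < config.herb_reuse_prob:
                members.add(pool_used[herb_rng.integers(len(pool_used))])
            elif unused:
                pick = unused.pop(herb_rng.integers(len(unused)))
                members.add(pick)
                used.append(pick)
            elif pool_used:
                members.add(pool_used[herb_rng.integers(len(pool_used))])
            else:
                break
        role = "JunChen" if h < math.ceil(config.n_herbs / 2) else "ZuoShi"
        herbs.append(
            HerbFormula(f"H{h + 1:02d}", f"Herb-{h + 1}", frozenset(members), role)
        )

    # physicochemical and ADMET annotations: plausible small-molecule ranges
    pc_rng = rng["physchem"]
    compounds = []
    for cid in compound_ids:
        mw = float(np.round(pc_rng.lognormal(mean=5.6, sigma=0.35), 2))  # ~190-450 Da bulk
        alogp = float(np.round(pc_rng.normal(2.0, 1.5), 2))
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                name=f"compound-{cid}",
                physchem=PhyschemProfile(
                    mw=mw,
                    alogp=alogp,
                    hbd=int(pc_rng.integers(0, 6)),
                    hba=int(pc_rng.integers(0, 11)),
                ),
                admet=AdmetScores(
                    hia_prob=float(np.round(pc_rng.random(), 3)),
                    bbb_prob=float(np.round(pc_rng.random(), 3)),
                ),
            )
        )

    return SyntheticDataset(
        config=config,
        compounds=compounds,
        herbs=herbs,
        fingerprints=fingerprints,
        dtis=dtis,
        disease=disease,
        planted=planted,
        driver_bits=driver_bits,
    )


def null_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Structureless control: no planted actives, no coupling."""
    return generate(replace(config, n_planted=0, coupling=0.0))


def holdout_split(
    dtis: Sequence[DTIRecord], fraction: float, seed: int
) -> tuple[list[DTIRecord], list[DTIRecord]]:
    """Seeded disjoint train/test partition of a DTI edge list.

    The test part holds ``ceil(fraction * n)`` edges.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    n = len(dtis)
    if n < 2:
        raise ValueError("need at least 2 DTIs to split")
    n_test = math.ceil(fraction * n)
    order = np.random.default_rng(seed).permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [r for i, r in enumerate(dtis) if i not in test_idx]
    test = [r for i, r in enumerate(dtis) if i in test_idx]
    return train, test
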