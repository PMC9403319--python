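"""Synthetic glycan-microarray experiments with known ground truth.

The generator emulates a CFG-style dose-response experiment: one GPR
file per protein concentration, each glycan printed in 6 replicate
spots, spot signal drawn around the one-site isotherm
Bmax·c/(Kd + c) with multiplicative Gaussian replicate noise
(CV-parameterised) on top of an additive Gaussian background.  Every run
emits standard GPR files (the same dialect :mod:`glycofit.gpr` writes),
a CSV truth table of the generating parameters, a matching glycan
catalog and a ready-made run config — so every pipeline stage can be
exercised, and parameter recovery checked, without real array data.

All randomness flows from a single recorded seed; the same seed
reproduces the same files byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import (
    GlycanAnnotation,
    GlycanCatalog,
    LinkageClass,
    StructureGroup,
    write_catalog,
)
from .gpr import GprFile, SpotRecord, write_gpr

__all__ = [
    "DEFAULT_LADDER",
    "NoiseSpec",
    "TruthRecord",
    "SimulatedExperiment",
    "expected_rfu",
    "make_catalog_fixture",
    "sample_truth",
    "generate_experiment",
]

#: Concentration ladder of the reference experiments: 0.04–10 µM in
#: 3-fold steps (10, 3.3, 1.1, 0.36, 0.12, 0.04), stored ascending.
DEFAULT_LADDER: tuple[float, ...] = (0.04, 0.12, 0.36, 1.1, 3.3, 10.0)

#: Default class mix of a simulated array: half the glycans saturate
#: inside the ladder, 0.3 bind without saturating, 0.2 do not bind.
DEFAULT_PROPORTIONS: tuple[float, float, float] = (0.5, 0.3, 0.2)


@dataclass(frozen=True)
class NoiseSpec:
    """Spot-level noise model.

    replicate_cv:
        Coefficient of variation of the multiplicative Gaussian noise on
        the binding signal (0.05 = 5% spot-to-spot scatter).
    background_mean, background_sd:
        Additive background fluorescence (RFU).  The foreground of a spot
        is background + signal·(1 + cv·z); the background *estimate*
        written to the file carries its own Gaussian error with this SD,
        so background-subtracted RFU is noisy even for nonbinders.
    seed:
        Seed of the single generator driving every draw.
    """

    replicate_cv: float = 0.05
    background_mean: float = 100.0
    background_sd: float = 20.0
    seed: int = 0


@dataclass(frozen=True)
class TruthRecord:
    glycan_id: str
    true_bmax: float  # RFU; 0 for nonbinders
    true_kd: float | None  # µM; None for nonbinders
    structure_group: StructureGroup
    linkage_class: LinkageClass


@dataclass
class SimulatedExperiment:
    files: list[tuple[Path, float]]  # (gpr path, concentration µM)
    truth: pd.DataFrame
    truth_path: Path
    catalog: GlycanCatalog
    catalog_path: Path
    config_path: Path


def expected_rfu(bmax: float, kd: float, concentration: float) -> float:
    """Noiseless spot signal at one concentration: Bmax·c/(Kd + c)."""
    return bmax * concentration / (kd + concentration)


# ---------------------------------------------------------------------------
# catalog fixture

_STRUCTURE_TEMPLATES: dict[StructureGroup, list[tuple[str, str, LinkageClass]]] = {
    # (structure template, terminal motif, linkage class); {i} = chart number
    StructureGroup.N_GLYCAN: [
        (
            "Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]"
            "Man(b1-4)GlcNAc(b1-4)GlcNAc-Sp{i}",
            "LacNAc",
            LinkageClass.TYPE2_LACNAC,
        ),
        (
            "Gal(b1-3)GlcNAc(b1-2)Man(a1-3)[Gal(b1-3)GlcNAc(b1-2)Man(a1-6)]"
            "Man(b1-4)GlcNAc(b1-4)GlcNAc-Sp{i}",
            "LacNAc",
            LinkageClass.TYPE1_LACNAC,
        ),
    ],
    StructureGroup.BLOOD_GROUP_ANTIGEN: [
        (
            "Fuc(a1-2)Gal(b1-3)GlcNAc(b1-3)Gal(b1-4)Glc-Sp{i}",
            "H antigen",
            LinkageClass.TYPE1_LACNAC,
        ),
        (
            "Fuc(a1-2)Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc-Sp{i}",
            "H antigen",
            LinkageClass.TYPE2_LACNAC,
        ),
    ],
    StructureGroup.SIALIC_ACID: [
        (
            "Neu5Ac(a2-3)Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc-Sp{i}",
            "Neu5Ac a2-3",
            LinkageClass.TYPE2_LACNAC,
        ),
        (
            "Neu5Ac(a2-6)Gal(b1-3)GlcNAc(b1-3)Gal(b1-4)Glc-Sp{i}",
            "Neu5Ac a2-6",
            LinkageClass.TYPE1_LACNAC,
        ),
    ],
    StructureGroup.OTHER: [
        ("Glc(a1-4)Glc(a1-4)Glc-Sp{i}", "glucan", LinkageClass.OTHER),
        ("Man(a1-2)Man(a1-2)Man-Sp{i}", "oligomannose", LinkageClass.OTHER),
    ],
}

_GROUPS = (
    StructureGroup.N_GLYCAN,
    StructureGroup.BLOOD_GROUP_ANTIGEN,
    StructureGroup.SIALIC_ACID,
    StructureGroup.OTHER,
)


def _allocate(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n items over the proportions."""
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {sum(proportions)}")
    raw = [n * p for p in proportions]
    counts = [int(x) for x in raw]
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    return counts


def make_catalog_fixture(
    n_glycans: int,
    group_proportions: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1),
    version_label: str = "synthetic-catalog",
) -> GlycanCatalog:
    """Deterministic catalog whose structure strings embed the motifs the
    group classifier keys on, cross-validating catalog and classifier.

    ``group_proportions`` order: N_glycan, blood_group_antigen,
    sialic_acid, other.  Allocation is deterministic (largest remainder),
    assigned in consecutive chart-number blocks.
    """
    counts = _allocate(n_glycans, group_proportions)
    anns: dict[int, GlycanAnnotation] = {}
    chart = 1
    for group, count in zip(_GROUPS, counts):
        templates = _STRUCTURE_TEMPLATES[group]
        for j in range(count):
            template, motif, linkage = templates[j % len(templates)]
            anns[chart] = GlycanAnnotation(
                chart_number=chart,
                structure=template.format(i=chart),
                linkage_class=linkage,
                structure_group=group,
                terminal_motif=motif,
            )
            chart += 1
    return GlycanCatalog(version_label=version_label, annotations=anns)


# ---------------------------------------------------------------------------
# truth sampling

def sample_truth(
    n_glycans: int,
    rng: np.random.Generator,
    proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS,
    kd_saturated: tuple[float, float] = (0.05, 1.0),
    kd_unsaturated: tuple[float, float] = (30.0, 300.0),
    bmax_range: tuple[float, float] = (1e3, 6e4),
    catalog: GlycanCatalog | None = None,
    kd_choices: tuple[float, ...] | None = None,
) -> list[TruthRecord]:
    """Draw generating parameters for each glycan.

    ``proportions`` = (saturating, unsaturated-range, nonbinder) class
    mix.  Kd is log-uniform within the class range (or uniformly chosen
    from ``kd_choices`` when given); Bmax is log-uniform over
    ``bmax_range``.  Nonbinders get Bmax = 0.
    """
    counts = _allocate(n_glycans, proportions)
    classes = (
        ["saturated_range"] * counts[0]
        + ["unsaturated_range"] * counts[1]
        + ["nonbinder"] * counts[2]
    )
    cat = catalog.resolved() if catalog is not None else None
    records: list[TruthRecord] = []
    for i, cls in enumerate(classes, start=1):
        if cls == "nonbinder":
            bmax, kd = 0.0, None
        else:
            lo, hi = kd_saturated if cls == "saturated_range" else kd_unsaturated
            if kd_choices is not None and cls == "saturated_range":
                kd = float(rng.choice(kd_choices))
            else:
                kd = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            bmax = float(
                np.exp(rng.uniform(np.log(bmax_range[0]), np.log(bmax_range[1])))
            )
        if cat is not None and i in cat:
            ann = cat.get(i)
            group, linkage = ann.structure_group, ann.linkage_class
        else:
            group, linkage = StructureGroup.OTHER, LinkageClass.UNKNOWN
        records.append(
            TruthRecord(
                glycan_id=str(i),
                true_bmax=bmax,
                true_kd=kd,
                structure_group=group,
                linkage_class=linkage,
            )
        )
    return records


# ---------------------------------------------------------------------------
# experiment generation

def _truth_frame(records: list[TruthRecord], noise: NoiseSpec) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "glycan_id": r.glycan_id,
                "true_bmax": r.true_bmax,
                "true_kd": r.true_kd,
                "structure_group": r.structure_group.value,
                "linkage_class": r.linkage_class.value,
                "seed": noise.seed,
            }
            for r in records
        ],
        columns=["glycan_id", "true_bmax", "true_kd", "structure_group",
                 "linkage_class", "seed"],
    )


def generate_experiment(
    outdir: str | Path,
    n_glycans: int = 555,
    ladder: tuple[float, ...] = DEFAULT_LADDER,
    proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS,
    noise: NoiseSpec = NoiseSpec(),
    n_replicates: int = 6,
    protein_name: str = "synthetic-GBP",
    group_proportions: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1),
    kd_saturated: tuple[float, float] = (0.05, 1.0),
    kd_unsaturated: tuple[float, float] = (30.0, 300.0),
    bmax_range: tuple[float, float] = (1e3, 6e4),
    kd_choices: tuple[float, ...] | None = None,
) -> SimulatedExperiment:
    """Write a complete synthetic experiment under ``outdir``.

    Emits one GPR file per ladder concentration (``{protein}_{c}uM.gpr``),
    ``truth.csv``, ``catalog.csv`` and ``config.yaml``.  Deterministic in
    ``noise.seed``: identical seeds produce byte-identical files.
    """
    if n_glycans < 1:
        raise ValueError("n_glycans must be >= 1")
    if len(ladder) < 2:
        raise ValueError("ladder needs >= 2 concentrations to support fits")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ladder = tuple(sorted(ladder))

    rng = np.random.default_rng(noise.seed)
    catalog = make_catalog_fixture(n_glycans, group_proportions)
    records = sample_truth(
        n_glycans,
        rng,
        proportions,
        kd_saturated=kd_saturated,
        kd_unsaturated=kd_unsaturated,
        bmax_range=bmax_range,
        catalog=catalog,
        kd_choices=kd_choices,
    )

    files: list[tuple[Path, float]] = []
    for conc in ladder:
        spots: list[SpotRecord] = []
        for row, rec in enumerate(records, start=1):
            signal = (
                0.0
                if rec.true_kd is None
                else expected_rfu(rec.true_bmax, rec.true_kd, conc)
            )
            for rep in range(1, n_replicates + 1):
                bg_true = max(
                    0.0, noise.background_mean + noise.background_sd * rng.standard_normal()
                )
                fg = bg_true + signal * (1.0 + noise.replicate_cv * rng.standard_normal())
                bg_est = max(
                    0.0, noise.background_mean + noise.background_sd * rng.standard_normal()
                )
                spots.append(
                    SpotRecord(
                        block=1,
                        column=rep,
                        row=row,
                        name=f"Glycan {rec.glycan_id}",
                        glycan_id=rec.glycan_id,
                        foreground=max(0.0, fg),
                        background=bg_est,
                        flag=0,
                    )
                )
        gpr = GprFile(
            header={
                "Type": "GenePix Results 3",
                "Wavelengths": "488",
                "Creator": "glycofit simulate",
                "Protein": protein_name,
                "ConcentrationUM": f"{conc:g}",
            },
            spots=spots,
            wavelength=488,
        )
        path = outdir / f"{protein_name}_{conc:g}uM.gpr"
        write_gpr(gpr, path)
        files.append((path, conc))

    truth = _truth_frame(records, noise)
    truth_path = outdir / "truth.csv"
    truth.to_csv(truth_path, index=False)

    catalog_path = outdir / "catalog.csv"
    write_catalog(catalog, catalog_path)

    config = {
        "protein": protein_name,
        "input_dir": ".",
        "files": [
            {"file": p.name, "concentration": float(c)} for p, c in files
        ],
        "catalog": catalog_path.name,
        "truth": truth_path.name,
        "seed": noise.seed,
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    return SimulatedExperiment(
        files=files,
        truth=truth,
        truth_path=truth_path,
        catalog=catalog,
        catalog_path=catalog_path,
        config_path=config_path,
    )
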