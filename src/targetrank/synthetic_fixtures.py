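"""Self-contained synthetic test projects with planted ideal targets.

The generator emulates the data an analyst would assemble for target
prioritization: per-phenotype tumor expression matrices (lognormal
baseline on the log2 scale), a normal-tissue expression snapshot, a
surface-localization evidence table, a phenotype-tagged dependency
snapshot, a reagent/drug record table, and a molecular-target-list
flag. A small set of *planted* genes per phenotype receives the ideal
target profile — elevated, homogeneous tumor expression; suppressed
normal-tissue expression; high surface evidence; elevated dependency;
and drug records that turn them into known positives — while decoy
genes get discontinued-only records and become known negatives.

Ground truth lives only in the manifest, never in the feature tables,
so enrichment cannot leak it. Everything is reproducible from the seed:
the same configuration writes byte-identical directories.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ExpressionDataset,
    FeatureSnapshot,
    LabelSet,
    ValidationError,
)
from .feature_enrichment import derive_labels

__all__ = ["FixtureConfig", "FixtureProject", "build_projects",
           "generate_fixture", "fixture_truth", "load_fixture"]

N_TISSUES = 8
N_LINES_PER_PHENOTYPE = 3


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic benchmark.

    Defaults encode a strong, clearly recoverable planted signal: a
    tumor shift of 2 noise standard deviations, four-fold normal-tissue
    suppression, 0.9 probability of top surface evidence, full drug
    coverage of planted genes and 30% discontinued decoys.
    """

    n_genes: int = 1000
    n_samples: int = 20
    n_phenotypes: int = 2
    n_planted: int = 10
    tumor_effect_sd: float = 2.0   # log2 shift of planted genes, in noise-sd units
    normal_suppression: float = 4.0  # fold-reduction of planted genes in normal tissue
    surface_boost_p: float = 0.9   # P(planted gene gets top surface evidence)
    dependency_boost: float = 0.5  # added dependency effect of planted genes
    drug_coverage: float = 1.0     # fraction of planted genes given active drug records
    decoy_fraction: float = 0.3    # discontinued-only decoys, as a fraction of n_planted
    noise_sd: float = 1.0          # log2-scale sample noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted >= self.n_genes:
            raise ValidationError("n_planted must be smaller than n_genes")
        for name in ("surface_boost_p", "drug_coverage", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.seed is None or int(self.seed) < 0:
            raise ValidationError("a nonnegative seed is mandatory")
        if min(self.n_genes, self.n_samples, self.n_phenotypes, self.n_planted) < 1:
            raise ValidationError("counts must be positive")


@dataclass
class FixtureProject:
    """In-memory bundle for one phenotype: dataset, snapshots, labels, truth."""

    dataset: ExpressionDataset
    snapshots: dict[str, FeatureSnapshot]
    labels: LabelSet
    planted: list[str]
    decoys: list[str] = field(default_factory=list)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"GENE{i:0{width}d}" for i in range(1, n + 1)]


def _phenotype_names(n: int) -> list[str]:
    return [f"PHENO{i}" for i in range(1, n + 1)]


def build_projects(cfg: FixtureConfig) -> list[FixtureProject]:
    """Generate the synthetic study in memory, one project per phenotype."""
    rng = np.random.default_rng(cfg.seed)
    genes = np.array(_gene_names(cfg.n_genes), dtype=object)
    phenotypes = _phenotype_names(cfg.n_phenotypes)

    # non-overlapping planted sets, one per phenotype
    need = cfg.n_planted * cfg.n_phenotypes
    if need > cfg.n_genes:
        raise ValidationError("not enough genes for disjoint planted sets")
    chosen = rng.choice(cfg.n_genes, size=need, replace=False)
    planted = {ph: sorted(genes[chosen[i * cfg.n_planted:(i + 1) * cfg.n_planted]])
               for i, ph in enumerate(phenotypes)}
    all_planted = sorted(set().union(*planted.values()))
    planted_mask = np.isin(genes, all_planted)

    base = rng.normal(5.0, 2.0, size=cfg.n_genes)  # per-gene log2 baseline
    shift = cfg.tumor_effect_sd * cfg.noise_sd

    # --- expression matrices (log2 intensities) -------------------------
    datasets = {}
    for ph in phenotypes:
        mat = base[:, None] + rng.normal(0.0, cfg.noise_sd,
                                         size=(cfg.n_genes, cfg.n_samples))
        mat[np.isin(genes, planted[ph])] += shift
        samples = [f"{ph}_S{j:02d}" for j in range(1, cfg.n_samples + 1)]
        df = pd.DataFrame(np.round(mat, 6), index=genes, columns=samples)
        datasets[ph] = ExpressionDataset(values=df, phenotype=ph, units="log2",
                                         metadata={"source": "synthetic"})

    # --- normal-tissue snapshot (linear scale) --------------------------
    tissues = [f"tissue_{t}" for t in range(1, N_TISSUES + 1)]
    normal_log = base[:, None] + rng.normal(0.0, 1.0, size=(cfg.n_genes, N_TISSUES))
    normal = np.power(2.0, normal_log)
    normal[planted_mask] /= cfg.normal_suppression
    gtex = pd.DataFrame(np.round(normal, 4), index=genes, columns=tissues)

    # --- surface-localization evidence (0-5) ----------------------------
    evidence = rng.binomial(5, 0.3, size=cfg.n_genes).astype(float)
    boost = rng.random(cfg.n_genes) < cfg.surface_boost_p
    evidence[planted_mask & boost] = 5.0
    surface = pd.DataFrame({"evidence_score": evidence}, index=genes)
    # realistic sparsity: ~5% of background genes were never assayed
    drop = (rng.random(cfg.n_genes) < 0.05) & ~planted_mask
    surface = surface.loc[~drop]

    # --- dependency snapshot, phenotype-tagged cell lines ---------------
    dep_cols = {}
    for ph in phenotypes:
        mask = np.isin(genes, planted[ph])
        for j in range(1, N_LINES_PER_PHENOTYPE + 1):
            col = np.abs(rng.normal(0.0, 0.3, size=cfg.n_genes))
            col[mask] += cfg.dependency_boost
            dep_cols[f"{ph}.L{j}"] = np.round(col, 4)
    depmap = pd.DataFrame(dep_cols, index=genes)

    # --- molecular-target-list flag -------------------------------------
    pmtl = (rng.random(cfg.n_genes) < 0.02).astype(float)
    pmtl[planted_mask & (rng.random(cfg.n_genes) < 0.5)] = 1.0
    pmtl_df = pd.DataFrame({"pmtl": pmtl}, index=genes)

    # --- drug records: planted -> active, decoys -> discontinued --------
    records = []
    decoys: dict[str, list[str]] = {}
    n_decoys = int(round(cfg.decoy_fraction * cfg.n_planted))
    background = [g for g in genes if g not in all_planted]
    for ph in phenotypes:
        for g in planted[ph]:
            if rng.random() < cfg.drug_coverage:
                modality = ["ADC", "CAR-T", "mAb"][int(rng.integers(0, 3))]
                status = ["approved", "clinical"][int(rng.integers(0, 2))]
                records.append((g, ph, modality, status))
        picks = rng.choice(len(background), size=n_decoys, replace=False)
        decoys[ph] = sorted(background[i] for i in picks)
        background = [g for g in background if g not in set(decoys[ph])]
        for g in decoys[ph]:
            modality = ["ADC", "CAR-T", "mAb"][int(rng.integers(0, 3))]
            records.append((g, ph, modality, "discontinued"))
    drug = pd.DataFrame(records, columns=["gene", "phenotype", "modality", "status"])

    snapshots = {
        "gtex_like": FeatureSnapshot("gtex_like", gtex, schema="gtex_like"),
        "surface_evidence": FeatureSnapshot("surface_evidence", surface,
                                            schema="surface_evidence"),
        "depmap_like": FeatureSnapshot("depmap_like", depmap, schema="depmap_like"),
        "pmtl_like": FeatureSnapshot("pmtl_like", pmtl_df, schema="pmtl_like"),
        "drugdb": FeatureSnapshot("drugdb", drug, schema="drugdb"),
    }

    projects = []
    for ph in phenotypes:
        labels = derive_labels(ph, snapshots["drugdb"])
        projects.append(FixtureProject(
            dataset=datasets[ph],
            snapshots=snapshots,
            labels=labels,
            planted=planted[ph],
            decoys=decoys[ph],
        ))
    return projects


def generate_fixture(cfg: FixtureConfig, outdir: str | Path) -> Path:
    """Write a complete project directory; byte-identical for equal configs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    projects = build_projects(cfg)
    snapshots = projects[0].snapshots

    files = {}
    for proj in projects:
        name = f"expression_{proj.dataset.phenotype}.tsv"
        proj.dataset.values.to_csv(outdir / name, sep="\t", index_label="gene")
        files[proj.dataset.phenotype] = name
    for name, snap in snapshots.items():
        if snap.schema == "drugdb":
            snap.table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        else:
            snap.table.to_csv(outdir / f"{name}.tsv", sep="\t", index_label="gene")

    manifest = {
        "config": asdict(cfg),
        "expression_files": files,
        "snapshot_files": {n: f"{n}.tsv" for n in snapshots},
        "truth": {
            proj.dataset.phenotype: {
                "planted": list(proj.planted),
                "positives": sorted(proj.labels.positives),
                "negatives": sorted(proj.labels.negatives),
                "decoys": list(proj.decoys),
            }
            for proj in projects
        },
    }
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True, default_flow_style=False))

    # a ready-to-run project parameters file for the CLI
    project_yaml = {
        "datasets": [
            {"path": files[ph], "phenotype": ph, "units": "log2", "format": "tsv"}
            for ph in files
        ],
        "snapshots": {n: {"path": f"{n}.tsv", "schema": n} for n in snapshots},
        "labels": {"source": "drug_snapshot"},
        "seed": int(cfg.seed),
    }
    (outdir / "project.yaml").write_text(
        yaml.safe_dump(project_yaml, sort_keys=True, default_flow_style=False))
    return outdir


def fixture_truth(path: str | Path) -> dict:
    """Read ground truth back from a fixture directory or manifest file.

    Returns ``{phenotype: {"labels": LabelSet, "planted": [...],
    "decoys": [...]}}`` plus the generating config under ``"config"``.
    """
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.yaml"
    try:
        manifest = yaml.safe_load(path.read_text())
        truth = manifest["truth"]
        out: dict = {"config": manifest.get("config", {})}
        for ph, t in truth.items():
            out[ph] = {
                "labels": LabelSet(positives=frozenset(t["positives"]),
                                   negatives=frozenset(t["negatives"]),
                                   phenotype=ph, provenance="drug_snapshot"),
                "planted": list(t["planted"]),
                "decoys": list(t.get("decoys", [])),
            }
    except (OSError, yaml.YAMLError, KeyError, TypeError, AttributeError) as exc:
        raise ValidationError(f"corrupt or missing manifest at {path}: {exc}") from exc
    return out


def load_fixture(outdir: str | Path) -> list[FixtureProject]:
    """Reload a generated fixture directory through the standard readers."""
    from .feature_enrichment import load_snapshot
    from .project_io import read_expression

    outdir = Path(outdir)
    manifest = yaml.safe_load((outdir / "manifest.yaml").read_text())
    snapshots = {
        name: load_snapshot(outdir / fname, name)
        for name, fname in manifest["snapshot_files"].items()
    }
    truth = fixture_truth(outdir)
    projects = []
    for ph, fname in manifest["expression_files"].items():
        ds = read_expression(outdir / fname, format="tsv", units="log2",
                             phenotype=ph)
        projects.append(FixtureProject(
            dataset=ds,
            snapshots=snapshots,
            labels=truth[ph]["labels"],
            planted=truth[ph]["planted"],
            decoys=truth[ph]["decoys"],
        ))
    return projects
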