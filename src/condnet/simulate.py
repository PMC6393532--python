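"""Synthetic condition-annotated GEMs, and the published edge-table fixtures.

The generator plants the structure the pipeline is meant to find in real
tumor cohorts: sample groups with categorical attributes (cancer type,
tissue type, stage, vital status), driver-mutation flags honoring the
VHL/PBRM1/BAP1 co-occurrence and mutual-exclusivity pattern, globally
coexpressed gene modules, gene pairs correlated *only* within a
designated sample subset (with a condition-specific expression shift, as
differential expression produces in practice), independent background
genes, and a few distribution-shifted outlier samples.  Expression is
built on a Gaussian log2 scale and exponentiated to an FPKM-like
nonnegative scale so the preprocessing stages act nontrivially.

The module also packages, as checksummed TSV fixtures, the two published
edge tables for KIRC tumors with co-occurring VHL+BAP1 and VHL+PBRM1
driver mutations, plus the counting helpers used on them.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .enrichment import MUTATION, NO_MUTATION, SampleAnnotations

__all__ = [
    "GeneratorConfig",
    "PlantedEdge",
    "SyntheticTruth",
    "generate",
    "PrintedEdgeTable",
    "load_printed_table",
    "count_edges_with_gene",
    "count_ncRNA_genes",
]

MUTATION_PANEL = [
    "VHL", "PBRM1", "SETD2", "KDM5C", "BAP1", "PTEN", "MTOR", "TP53",
    "PIK3CA", "MET", "FAT1", "NF2", "KDM6A", "SMARCB1", "NFE2L2", "STAG2",
]

# marginal mutation rates among primary-tumor samples (KIRC co-occurrence
# genes are assigned by group instead)
_INDEPENDENT_MUTATION_RATES = {
    "SETD2": 0.12, "KDM5C": 0.06, "PTEN": 0.04, "MTOR": 0.06, "TP53": 0.05,
    "PIK3CA": 0.03, "MET": 0.05, "FAT1": 0.03, "NF2": 0.03, "KDM6A": 0.03,
    "SMARCB1": 0.02, "NFE2L2": 0.02, "STAG2": 0.02,
}

# driver-path groups among KIRC primary tumors: VHL initiates; PBRM1 and
# BAP1 branches are near-mutually exclusive, with a rare co-mutated clone
_KIRC_DRIVER_GROUPS = {
    "none": 0.20,
    "VHL_only": 0.20,
    "VHL_PBRM1": 0.35,
    "VHL_BAP1": 0.10,
    "VHL_PBRM1_BAP1": 0.02,
    "PBRM1_only": 0.08,
    "BAP1_only": 0.05,
}


@dataclass(frozen=True)
class PlantedEdge:
    """A gene pair correlated only inside its active sample subset."""

    gene_a: str
    gene_b: str
    rho: float
    condition: str  # attribute "column=value" key or mutation-group name


@dataclass
class GeneratorConfig:
    n_samples: int = 300
    n_genes: int = 150
    cancer_type_proportions: dict = field(
        default_factory=lambda: {"KIRC": 0.55, "KIRP": 0.30, "KICH": 0.15}
    )
    normal_tissue_fraction: float = 0.20
    tumor_stage_proportions: dict = field(
        default_factory=lambda: {
            "stage i": 0.40, "stage ii": 0.15, "stage iii": 0.25, "stage iv": 0.20
        }
    )
    vital_alive_fraction: float = 0.70
    kirc_driver_group_proportions: dict = field(
        default_factory=lambda: dict(_KIRC_DRIVER_GROUPS)
    )
    independent_mutation_rates: dict = field(
        default_factory=lambda: dict(_INDEPENDENT_MUTATION_RATES)
    )
    n_planted_edges: int = 20
    planted_rho: float = 0.95
    planted_shift: float = 3.0
    planted_conditions: tuple = (
        "tissue_type=Primary Tumor",
        "tissue_type=Solid Tissue Normal",
        "cancer_type=KIRC",
        "cancer_type=KIRP",
        "VHL_PBRM1",
    )
    n_global_modules: int = 5
    global_module_size: int = 8
    global_rho: float = 0.90
    n_outliers: int = 3
    outlier_shift: float = 5.0
    base_mean: float = 6.0
    base_mean_sd: float = 0.25
    noise_sd: float = 1.0
    min_detectable_subset: int = 30
    seed: int = 0

    def __post_init__(self):
        for name, props in (
            ("cancer_type_proportions", self.cancer_type_proportions),
            ("tumor_stage_proportions", self.tumor_stage_proportions),
            ("kirc_driver_group_proportions", self.kirc_driver_group_proportions),
        ):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
        if not abs(self.planted_rho) < 1.0:
            raise ValueError("planted rho magnitude must be < 1")
        needed = (self.n_global_modules * self.global_module_size
                  + 2 * self.n_planted_edges)
        if needed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small: modules and planted "
                f"edges require {needed} genes"
            )


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated dataset."""

    annotations: SampleAnnotations
    driver_groups: pd.Series
    planted: list[PlantedEdge]
    planted_masks: dict[tuple[str, str], np.ndarray]
    module_genes: list[list[str]]
    outlier_ids: list[str]
    config: GeneratorConfig

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(e.gene_a, e.gene_b) for e in self.planted}

    def manifest(self) -> dict:
        return {
            "outliers": self.outlier_ids,
            "modules": self.module_genes,
            "planted": [asdict(e) for e in self.planted],
        }


def _gene_id(i: int) -> str:
    return f"ENSG{i:011d};SYN{i:03d}"


def _choice(rng, options: dict, size: int) -> np.ndarray:
    keys = list(options)
    probs = np.array([options[k] for k in keys], dtype=float)
    return rng.choice(keys, size=size, p=probs / probs.sum())


def _condition_mask(
    cond: str, attrs: pd.DataFrame, groups: pd.Series
) -> np.ndarray:
    if "=" in cond:
        col, val = cond.split("=", 1)
        return (attrs[col].astype(str) == val).to_numpy()
    # mutation-group condition: group name matches exactly, or the
    # multi-clone group when it carries both drivers of `cond`
    return (groups == cond).to_numpy()


def generate(
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, SampleAnnotations, SyntheticTruth]:
    """Draw one synthetic dataset; bitwise reproducible from the seed."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes

    sample_ids = [f"S{i:04d}" for i in range(n)]
    cancer = _choice(rng, config.cancer_type_proportions, n)
    is_normal = rng.random(n) < config.normal_tissue_fraction
    tissue = np.where(is_normal, "Solid Tissue Normal", "Primary Tumor")
    stage = np.where(
        is_normal, "not reported", _choice(rng, config.tumor_stage_proportions, n)
    )
    vital = np.where(rng.random(n) < config.vital_alive_fraction, "alive", "dead")
    attrs = pd.DataFrame(
        {
            "cancer_type": cancer,
            "tissue_type": tissue,
            "tumor_stage": stage,
            "vital_status": vital,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # driver groups among KIRC primary tumors; everyone else "none"
    groups = pd.Series("none", index=attrs.index)
    kirc_tumor = (cancer == "KIRC") & ~is_normal
    groups[kirc_tumor] = _choice(
        rng, config.kirc_driver_group_proportions, int(kirc_tumor.sum())
    )
    mut = pd.DataFrame(NO_MUTATION, index=attrs.index, columns=MUTATION_PANEL)
    has_vhl = groups.str.startswith("VHL")
    mut.loc[has_vhl, "VHL"] = MUTATION
    mut.loc[groups.isin(["VHL_PBRM1", "VHL_PBRM1_BAP1", "PBRM1_only"]), "PBRM1"] = MUTATION
    mut.loc[groups.isin(["VHL_BAP1", "VHL_PBRM1_BAP1", "BAP1_only"]), "BAP1"] = MUTATION
    tumor = ~is_normal
    for gene, rate in config.independent_mutation_rates.items():
        hit = tumor & (rng.random(n) < rate)
        mut.loc[hit, gene] = MUTATION
    ann = SampleAnnotations(attributes=attrs, mutations=mut)

    outlier_ids = list(rng.choice(sample_ids, size=config.n_outliers, replace=False))
    outlier_pos = attrs.index.get_indexer(outlier_ids)
    not_outlier = np.ones(n, dtype=bool)
    not_outlier[outlier_pos] = False

    gene_ids = [_gene_id(i) for i in range(g)]
    mu = config.base_mean + config.base_mean_sd * rng.standard_normal(g)
    x = mu[:, None] + config.noise_sd * rng.standard_normal((g, n))

    # globally coexpressed modules occupy the first genes
    module_genes: list[list[str]] = []
    cursor = 0
    for _m in range(config.n_global_modules):
        members = list(range(cursor, cursor + config.global_module_size))
        cursor += config.global_module_size
        z = rng.standard_normal(n)
        r = config.global_rho
        for gi in members:
            eps = rng.standard_normal(n)
            x[gi] = mu[gi] + config.noise_sd * (
                np.sqrt(r) * z + np.sqrt(1.0 - r) * eps
            )
        module_genes.append([gene_ids[i] for i in members])

    # condition-specific planted pairs take the next genes
    planted: list[PlantedEdge] = []
    planted_masks: dict[tuple[str, str], np.ndarray] = {}
    for e in range(config.n_planted_edges):
        ga, gb = cursor, cursor + 1
        cursor += 2
        if cursor > g:
            raise ValueError("n_genes too small for the requested planted edges")
        cond = config.planted_conditions[e % len(config.planted_conditions)]
        active = _condition_mask(cond, attrs, groups) & not_outlier
        n_active = int(active.sum())
        if n_active < config.min_detectable_subset:
            warnings.warn(
                f"planted edge {e}: active subset for {cond!r} has "
                f"{n_active} samples (< {config.min_detectable_subset}); "
                "undetectable by design",
                RuntimeWarning,
                stacklevel=2,
            )
        r = abs(config.planted_rho)
        sign = np.sign(config.planted_rho)
        z = rng.standard_normal(n_active)
        for gi, s in ((ga, 1.0), (gb, sign)):
            eps = rng.standard_normal(n_active)
            x[gi, active] = (
                mu[gi]
                + config.planted_shift
                + config.noise_sd * (s * np.sqrt(r) * z + np.sqrt(1.0 - r) * eps)
            )
        edge = PlantedEdge(gene_ids[ga], gene_ids[gb], config.planted_rho, cond)
        planted.append(edge)
        planted_masks[(edge.gene_a, edge.gene_b)] = active.copy()

    x[:, outlier_pos] += config.outlier_shift

    fpkm = np.maximum(np.exp2(x) - 1.0, 0.0)
    gem = pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"),
                       columns=sample_ids)
    truth = SyntheticTruth(
        annotations=ann,
        driver_groups=groups,
        planted=planted,
        planted_masks=planted_masks,
        module_genes=module_genes,
        outlier_ids=outlier_ids,
        config=config,
    )
    return gem, ann, truth


def write_dataset(gem, ann: SampleAnnotations, truth: SyntheticTruth, outdir) -> None:
    """Persist a generated dataset: GEM TSV, annotation TSVs, truth JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gem.to_csv(outdir / "gem.tsv", sep="\t", na_rep="NA")
    ann.attributes.to_csv(outdir / "annotations.tsv", sep="\t")
    if ann.mutations is not None:
        ann.mutations.to_csv(outdir / "mutations.tsv", sep="\t")
    manifest = truth.manifest()
    manifest["planted_masks"] = {
        f"{a}|{b}": mask.astype(int).tolist()
        for (a, b), mask in truth.planted_masks.items()
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


# ---------------------------------------------------------------------------
# published edge-table fixtures

_TABLE_FILES = {
    "vhl_bap1": "vhl_bap1_edges.tsv",
    "vhl_pbrm1": "vhl_pbrm1_edges.tsv",
}
_TABLE_SHA256 = {
    "vhl_bap1": "08fabbab8b336b18fede30d0cad377923722fc84283dc31f6442abb43bea8d5b",
    "vhl_pbrm1": "40fb0654a677c072d821f73ac352dc8b63fdb1dab5fed07f9626c61d7122f953",
}
_NCRNA_MARKERS = ("antisense rna", "lincrna", "lncrna")


@dataclass
class PrintedEdgeTable:
    """One published edge table (gene pairs with descriptions and modules)."""

    name: str
    table: pd.DataFrame  # gene_a, gene_b, desc_a, desc_b, module, notes

    def __len__(self) -> int:
        return len(self.table)

    @staticmethod
    def _symbol(gene_id: str) -> str:
        return gene_id.split(";", 1)[1] if ";" in gene_id else gene_id

    def symbols(self) -> set[str]:
        out = set()
        for col in ("gene_a", "gene_b"):
            out.update(self._symbol(v) for v in self.table[col])
        return out

    def modules(self) -> set[str]:
        return {m for m in self.table["module"] if m != "NA"}


def load_printed_table(which: str) -> PrintedEdgeTable:
    """Load a packaged edge-table fixture, verifying its checksum."""
    if which not in _TABLE_FILES:
        raise KeyError(
            f"unknown table {which!r}; expected one of {sorted(_TABLE_FILES)}"
        )
    ref = resources.files("condnet").joinpath("data", _TABLE_FILES[which])
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE_SHA256[which]:
        raise RuntimeError(
            f"fixture {which} checksum mismatch: {digest} != {_TABLE_SHA256[which]}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t", dtype=str, keep_default_na=False)
    return PrintedEdgeTable(which, df)


def count_edges_with_gene(table: PrintedEdgeTable, symbol: str) -> int:
    """Rows whose gene_a or gene_b symbol equals ``symbol``."""
    sym = table._symbol
    hits = 0
    for _, row in table.table.iterrows():
        if sym(row["gene_a"]) == symbol or sym(row["gene_b"]) == symbol:
            hits += 1
    return hits


def count_ncRNA_genes(table: PrintedEdgeTable) -> int:
    """Distinct gene IDs whose description marks a non-coding RNA."""
    ids: set[str] = set()
    for _, row in table.table.iterrows():
        for gcol, dcol in (("gene_a", "desc_a"), ("gene_b", "desc_b")):
            if any(m in row[dcol].lower() for m in _NCRNA_MARKERS):
                ids.add(row[gcol])
    return len(ids)
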