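"""Synthetic paired methylation + expression bundles with known truth.

The generator emulates the statistical structure the pipeline assumes:
normal-referenced Gaussian beta values with planted hyper-/hypomethylation
in tumor subsets, cis expression effects anti-correlated with promoter
methylation, downstream expression programs drawn from pathway gene
sets, passenger alterations with no expression linkage, and
subtype-biased alteration frequencies. Beta values are truncated
Gaussians by default so the Z-score model is exactly correct under the
null; a Beta-distributed mode exists to probe robustness (no calibration
guarantees there).

It does not attempt to match real methylation-array probe distributions,
beta bimodality or batch effects.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import (
    ValidationError,
    write_annotation,
    write_edge_list,
    write_gene_list,
    write_gmt,
    write_matrix,
)

SUBTYPE_NAMES = ("basal-like", "luminal-A", "HER2+")


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Effects are in the units stated: ``meth_shift`` in beta units,
    ``cis_effect`` and ``downstream_effect`` in multiples of the
    expression noise standard deviation.
    """

    n_normal: int = 20
    n_tumor: int = 60
    n_loci: int = 500
    n_genes: int = 2000
    n_pathways: int = 20
    pathway_size: int = 50
    n_drivers: int = 10
    n_passengers: int = 50
    n_subtype_drivers: int = 3
    altered_fraction: float = 0.3
    meth_shift: float = 0.3
    beta_noise_sd: float = 0.05
    cis_effect: float = 1.5
    downstream_effect: float = 1.0
    program_size: int = 40
    n_subtypes: int = 3
    subtype_concentration: float = 0.85  # share of altered samples inside the home subtype
    n_cancer_genes: int = 100
    n_background_edges: int = 3000
    beta_mode: str = "truncated_gaussian"  # or "beta"
    loci_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci > self.n_genes * self.loci_per_gene:
            raise ValidationError("more loci than gene slots")
        if self.n_drivers + self.n_passengers > self.n_loci:
            raise ValidationError("more planted loci than loci")
        if self.program_size > self.pathway_size:
            raise ValidationError("downstream program larger than a pathway")
        if self.n_subtypes > len(SUBTYPE_NAMES):
            raise ValidationError(f"at most {len(SUBTYPE_NAMES)} subtypes supported")
        if self.beta_mode not in ("truncated_gaussian", "beta"):
            raise ValidationError("beta_mode must be 'truncated_gaussian' or 'beta'")
        n_alt = round(self.altered_fraction * self.n_tumor)
        if n_alt < 3 or self.n_tumor - n_alt < 3:
            raise ValidationError("altered fraction leaves a group below pipeline minimums")


@dataclass
class PlantedLocus:
    locus_id: str
    gene_id: str
    direction: str  # "hyper" | "hypo"
    altered_samples: tuple[str, ...]
    downstream_genes: tuple[str, ...] = ()
    target_pathways: tuple[str, ...] = ()
    home_subtype: str | None = None


@dataclass
class SyntheticTruth:
    drivers: list[PlantedLocus]
    passengers: list[PlantedLocus]
    subtype_of: dict[str, str]

    @property
    def driver_loci(self) -> frozenset[str]:
        return frozenset(d.locus_id for d in self.drivers)

    @property
    def driver_genes(self) -> frozenset[str]:
        return frozenset(d.gene_id for d in self.drivers)

    @property
    def passenger_loci(self) -> frozenset[str]:
        return frozenset(p.locus_id for p in self.passengers)

    def to_json(self, path) -> None:
        payload = {
            "drivers": [dataclasses.asdict(d) for d in self.drivers],
            "passengers": [dataclasses.asdict(p) for p in self.passengers],
            "subtype_of": self.subtype_of,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)

        def mk(rec):
            return PlantedLocus(
                locus_id=rec["locus_id"],
                gene_id=rec["gene_id"],
                direction=rec["direction"],
                altered_samples=tuple(rec["altered_samples"]),
                downstream_genes=tuple(rec["downstream_genes"]),
                target_pathways=tuple(rec["target_pathways"]),
                home_subtype=rec["home_subtype"],
            )

        return cls(
            drivers=[mk(r) for r in payload["drivers"]],
            passengers=[mk(r) for r in payload["passengers"]],
            subtype_of=dict(payload["subtype_of"]),
        )


@dataclass
class Bundle:
    methylation: pd.DataFrame  # loci x (normals + tumors)
    expression: pd.DataFrame  # genes x (normals + tumors)
    annotation: pd.DataFrame  # index locus_id; gene_id, chromosome
    samples: pd.DataFrame  # sample_id, group, subtype
    pathways: dict[str, frozenset[str]]
    cancer_genes: frozenset[str]
    network: nx.Graph
    truth: SyntheticTruth
    config: SimulationConfig = field(repr=False, default=None)


def _truncate_beta(values: np.ndarray) -> np.ndarray:
    return np.clip(values, 1e-3, 1.0 - 1e-3)


def generate(config: SimulationConfig) -> Bundle:
    """Draw one complete input bundle plus its ground truth."""
    c = config
    rng = np.random.default_rng(c.seed)

    genes = [f"G{i:04d}" for i in range(c.n_genes)]
    loci = [f"cg{i:05d}" for i in range(c.n_loci)]
    locus_gene = [genes[i // c.loci_per_gene] for i in range(c.n_loci)]
    annotation = pd.DataFrame(
        {
            "gene_id": locus_gene,
            "chromosome": [str((i % 22) + 1) for i in range(c.n_loci)],
        },
        index=pd.Index(loci, name="locus_id"),
    )

    normals = [f"N{i:03d}" for i in range(c.n_normal)]
    tumors = [f"T{i:03d}" for i in range(c.n_tumor)]
    subtype_names = list(SUBTYPE_NAMES[: c.n_subtypes])
    subtype_of = {t: subtype_names[i * c.n_subtypes // c.n_tumor] for i, t in enumerate(tumors)}
    samples = pd.DataFrame(
        {
            "sample_id": normals + tumors,
            "group": ["normal"] * c.n_normal + ["tumor"] * c.n_tumor,
            "subtype": [pd.NA] * c.n_normal + [subtype_of[t] for t in tumors],
        }
    )

    # pathways over the gene universe
    pathways = {
        f"pathway_{i:02d}": frozenset(rng.choice(genes, size=c.pathway_size, replace=False))
        for i in range(c.n_pathways)
    }
    pathway_names = sorted(pathways)

    # planted loci: drivers first, then passengers, all on distinct loci
    planted_idx = rng.choice(c.n_loci, size=c.n_drivers + c.n_passengers, replace=False)
    driver_idx = planted_idx[: c.n_drivers]
    passenger_idx = planted_idx[c.n_drivers :]

    n_alt = round(c.altered_fraction * c.n_tumor)
    by_subtype = {name: [t for t in tumors if subtype_of[t] == name] for name in subtype_names}

    def draw_altered(home: str | None) -> tuple[str, ...]:
        if home is None:
            return tuple(rng.choice(tumors, size=n_alt, replace=False))
        inside = by_subtype[home]
        n_in = min(int(np.ceil(c.subtype_concentration * n_alt)), len(inside))
        outside = [t for t in tumors if subtype_of[t] != home]
        picked = list(rng.choice(inside, size=n_in, replace=False)) + list(
            rng.choice(outside, size=n_alt - n_in, replace=False)
        )
        return tuple(picked)

    drivers: list[PlantedLocus] = []
    for j, idx in enumerate(driver_idx):
        locus, gene = loci[idx], locus_gene[idx]
        direction = "hyper" if rng.random() < 0.5 else "hypo"
        home = subtype_names[j % c.n_subtypes] if j < c.n_subtype_drivers else None
        n_targets = 1 + int(rng.random() < 0.5)
        targets = tuple(rng.choice(pathway_names, size=n_targets, replace=False))
        pool = sorted(set().union(*(pathways[t] for t in targets)) - {gene})
        program = tuple(rng.choice(pool, size=min(c.program_size, len(pool)), replace=False))
        drivers.append(
            PlantedLocus(
                locus_id=locus,
                gene_id=gene,
                direction=direction,
                altered_samples=draw_altered(home),
                downstream_genes=program,
                target_pathways=targets,
                home_subtype=home,
            )
        )

    passengers: list[PlantedLocus] = []
    for idx in passenger_idx:
        locus, gene = loci[idx], locus_gene[idx]
        direction = "hyper" if rng.random() < 0.5 else "hypo"
        passengers.append(
            PlantedLocus(
                locus_id=locus,
                gene_id=gene,
                direction=direction,
                altered_samples=draw_altered(None),
            )
        )

    # --- methylation ------------------------------------------------------
    mu = rng.uniform(0.2, 0.8, size=c.n_loci)
    n_samples = c.n_normal + c.n_tumor
    if c.beta_mode == "truncated_gaussian":
        beta = rng.normal(mu[:, None], c.beta_noise_sd, size=(c.n_loci, n_samples))
    else:
        # moment-matched Beta draws: same mean, dispersion set by beta_noise_sd
        var = c.beta_noise_sd**2
        nu = mu * (1 - mu) / var - 1
        a = np.maximum(mu * nu, 1e-2)
        b = np.maximum((1 - mu) * nu, 1e-2)
        beta = rng.beta(a[:, None], b[:, None], size=(c.n_loci, n_samples))
    meth = pd.DataFrame(beta, index=loci, columns=normals + tumors)
    sign = {"hyper": 1.0, "hypo": -1.0}
    for pl in drivers + passengers:
        meth.loc[pl.locus_id, list(pl.altered_samples)] += sign[pl.direction] * c.meth_shift
    meth = pd.DataFrame(
        _truncate_beta(meth.to_numpy()), index=meth.index, columns=meth.columns
    )

    # --- expression -------------------------------------------------------
    base = rng.uniform(6.0, 12.0, size=c.n_genes)
    expr = pd.DataFrame(
        base[:, None] + rng.normal(0.0, 1.0, size=(c.n_genes, n_samples)),
        index=genes,
        columns=normals + tumors,
    )
    for d in drivers:
        cols = list(d.altered_samples)
        # cis: expression moves opposite to the methylation direction
        expr.loc[d.gene_id, cols] -= sign[d.direction] * c.cis_effect
        signs = rng.choice([-1.0, 1.0], size=len(d.downstream_genes))
        for g, s in zip(d.downstream_genes, signs):
            expr.loc[g, cols] += s * c.downstream_effect

    # --- cancer genes and interaction network -----------------------------
    driver_genes = {d.gene_id for d in drivers}
    planted_genes = driver_genes | {p.gene_id for p in passengers}
    eligible = [g for g in genes if g not in planted_genes]
    cancer_genes = frozenset(rng.choice(eligible, size=c.n_cancer_genes, replace=False))
    network = nx.Graph()
    network.add_nodes_from(genes)
    cancer_sorted = sorted(cancer_genes)
    for d in sorted(driver_genes):
        for g in rng.choice(cancer_sorted, size=2, replace=False):
            network.add_edge(d, g)
    ii = rng.integers(0, c.n_genes, size=c.n_background_edges)
    jj = rng.integers(0, c.n_genes, size=c.n_background_edges)
    for i, j in zip(ii, jj):
        if i != j:
            network.add_edge(genes[i], genes[j])

    truth = SyntheticTruth(drivers=drivers, passengers=passengers, subtype_of=subtype_of)
    return Bundle(
        methylation=meth,
        expression=expr,
        annotation=annotation,
        samples=samples,
        pathways=pathways,
        cancer_genes=cancer_genes,
        network=network,
        truth=truth,
        config=c,
    )


def write_bundle(bundle: Bundle, outdir) -> dict[str, Path]:
    """Serialize a bundle into the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "methylation": outdir / "methylation.tsv",
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "samples": outdir / "samples.tsv",
        "pathways": outdir / "pathways.gmt",
        "cancer_genes": outdir / "cancer_genes.txt",
        "network": outdir / "network.tsv",
        "truth": outdir / "truth.json",
    }
    write_matrix(bundle.methylation, paths["methylation"])
    write_matrix(bundle.expression, paths["expression"])
    write_annotation(bundle.annotation, paths["annotation"])
    bundle.samples.to_csv(paths["samples"], sep="\t", index=False)
    write_gmt(bundle.pathways, paths["pathways"])
    write_gene_list(bundle.cancer_genes, paths["cancer_genes"])
    write_edge_list(bundle.network, paths["network"])
    bundle.truth.to_json(paths["truth"])
    return paths


@dataclass
class RecoveryScore:
    precision: float | None  # None when nothing was called
    recall: float
    n_called: int
    n_true: int
    n_hit: int


def score_recovery(called: frozenset[str], truth_positives: frozenset[str]) -> RecoveryScore:
    """Precision/recall of a called id set against planted positives."""
    called = frozenset(called)
    pos = frozenset(truth_positives)
    hit = len(called & pos)
    precision = hit / len(called) if called else None
    recall = hit / len(pos) if pos else 1.0
    return RecoveryScore(
        precision=precision, recall=recall, n_called=len(called), n_true=len(pos), n_hit=hit
    )


def block_ternary(
    n_blocks: int = 3,
    loci_per_block: int = 30,
    tumors_per_block: int = 20,
    signal_rate: float = 0.9,
    noise_rate: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted-partition ternary matrix: block b tumors altered at block b loci.

    Returns the loci x tumors matrix and the true block label per tumor.
    Used to exercise clustering recovery independently of the full
    generator.
    """
    rng = np.random.default_rng(seed)
    n_loci = n_blocks * loci_per_block
    n_tumors = n_blocks * tumors_per_block
    states = np.zeros((n_loci, n_tumors), dtype=np.int8)
    block_sign = [1 if b % 2 == 0 else -1 for b in range(n_blocks)]
    labels = np.repeat(np.arange(n_blocks), tumors_per_block)
    for b in range(n_blocks):
        rows = slice(b * loci_per_block, (b + 1) * loci_per_block)
        cols = np.flatnonzero(labels == b)
        mask = rng.random((loci_per_block, len(cols))) < signal_rate
        sub = np.where(mask, block_sign[b], 0).astype(np.int8)
        for j, cidx in enumerate(cols):
            states[rows, cidx] = sub[:, j]
    noise = rng.random(states.shape) < noise_rate
    flips = rng.choice([-1, 1], size=states.shape)
    states = np.where(noise & (states == 0), flips, states).astype(np.int8)
    loci = [f"cg{i:05d}" for i in range(n_loci)]
    tumors = [f"T{i:03d}" for i in range(n_tumors)]
    df = pd.DataFrame(states, index=loci, columns=tumors)
    return df, pd.Series(labels, index=tumors, name="block")
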