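"""Synthetic reciprocal-cross RNA-seq data with planted ground truth.

Three generators emulate the data structure of a reciprocal interploidy
wheat cross experiment (two cross directions, two biological replicates per
sample, embryo stages E1–E7 and endosperm stages E8–E9) so that every
downstream analysis can be exercised and benchmarked without real data:

* :func:`simulate_triads` — homoeolog triad expression with planted bias
  categories. Per triad, a category is drawn from configured proportions and
  a total expression level from a Gamma distribution; per-homoeolog counts
  are negative binomial around the category centroid's composition and
  converted to TPM.
* :func:`simulate_allele_counts` — maternal/paternal allele-specific counts
  with tissue dosage (expected maternal fraction 0.5 in embryo, 2/3 in
  endosperm) and planted MEGs/PEGs. The maternal role swaps parents between
  cross directions but the planted bias follows the maternal allele, so a
  true MEG is maternal-biased in both directions.
* :func:`simulate_isoform_quants` — isoform quantifications (quant.sf-style)
  for two groups with planted PSI shifts on a subset of isoforms.

One :class:`numpy.random.Generator` seeded from ``SimulationConfig.seed``
drives each generator, and the three generators use independent child seeds
in a fixed order, so adding one simulation stage never perturbs another's
draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    SampleMeta,
    ValidationError,
    tissue_for_stage,
)
from .triad_bias import default_centroids

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "simulate_triads",
    "simulate_allele_counts",
    "simulate_isoform_quants",
]

# parent ploidies used for sample metadata; cross labels are maternal-first
_PARENT_PLOIDY = {"A": 6, "Z": 6, "C": 4, "S": 4}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic reciprocal-cross experiment.

    Defaults describe the study conditions the generators emulate: 2,000
    triads with half balanced / 30% D-suppressed / 20% A-dominant planted
    categories, mean triad expression 300 TPM with negative-binomial
    dispersion 0.05, two biological replicates, allele-specific depth 100
    reads/gene with 1% MEGs and 1% PEGs at strength 0.95, and 100 isoforms
    (of ~2,000) with a planted PSI shift of 0.3.
    """

    seed: int = 0
    # triad simulation
    n_triads: int = 2000
    category_proportions: dict = field(
        default_factory=lambda: {"balanced": 0.5, "D_suppressed": 0.3, "A_dominant": 0.2}
    )
    triad_total_tpm_mean: float = 300.0
    nb_dispersion: float = 0.05
    n_replicates: int = 2
    stages: tuple = ("E3", "E8")
    cross_pair: tuple = ("AxC", "CxA")
    # allele-specific simulation
    n_genes_ase: int = 5000
    frac_meg: float = 0.01
    frac_peg: float = 0.01
    imprint_strength: float = 0.95
    ase_depth_mean: float = 100.0
    # isoform simulation
    n_isoform_genes: int = 667
    n_das_isoforms: int = 100
    delta_psi_planted: float = 0.3
    psi_noise_sigma: float = 0.15
    splicing_gene_tpm_mean: float = 50.0
    gamma_shape: float = 2.0
    library_size: float = 1e8

    def __post_init__(self):
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"category proportions sum to {total}, not 1")
        if not 0 <= self.frac_meg + self.frac_peg <= 1:
            raise ValidationError("frac_meg + frac_peg must lie in [0, 1]")
        if not 0.5 < self.imprint_strength <= 1.0:
            raise ValidationError("imprint_strength must lie in (0.5, 1]")
        if not 0.0 < self.delta_psi_planted <= 1.0:
            raise ValidationError("delta_psi_planted must lie in (0, 1]")
        if self.n_replicates < 1 or self.n_triads < 1:
            raise ValidationError("n_replicates and n_triads must be positive")
        for stage in self.stages:
            tissue_for_stage(stage)

    def _child_seed(self, stream: int) -> np.random.Generator:
        # fixed stream offsets keep the three generators independent
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class TruthLabels:
    """Planted ground truth for recovery benchmarking."""

    triad_category: dict = field(default_factory=dict)
    imprinting_status: dict = field(default_factory=dict)
    isoform_delta_psi: dict = field(default_factory=dict)


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with variance = mean + dispersion * mean^2 (zero-mean cells stay zero)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        raise ValidationError("nb_dispersion must be positive")
    n = 1.0 / dispersion
    p = n / (n + mean[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


def _sample_meta_for(cross: str, stage: str, replicate: int) -> SampleMeta:
    maternal, paternal = cross.split("x")
    return SampleMeta(
        sample_id=f"{cross}_{stage}_r{replicate}",
        cross=cross,
        maternal_parent=maternal,
        paternal_parent=paternal,
        maternal_ploidy=_PARENT_PLOIDY.get(maternal, 6),
        paternal_ploidy=_PARENT_PLOIDY.get(paternal, 6),
        tissue=tissue_for_stage(stage),
        stage=stage,
        replicate=replicate,
    )


def simulate_triads(config: SimulationConfig):
    """Simulate homoeolog triad expression with planted bias categories.

    Returns ``(ExpressionMatrix, triad_map, TruthLabels)``. Counts are drawn
    per replicate sample of each cross/stage with negative-binomial noise
    around ``total_expression × centroid``, then column-normalized to TPM.
    Deterministic given ``config.seed``.
    """
    rng = config._child_seed(1)
    centroids = default_centroids("3g").as_dict()
    for cat in config.category_proportions:
        if cat not in centroids:
            raise ValidationError(f"unknown bias category {cat!r}")

    cats = list(config.category_proportions)
    probs = np.array([config.category_proportions[c] for c in cats])
    planted = rng.choice(len(cats), size=config.n_triads, p=probs)
    planted_names = [cats[i] for i in planted]

    shape = config.gamma_shape
    totals = rng.gamma(shape, config.triad_total_tpm_mean / shape, size=config.n_triads)
    comp = np.stack([centroids[c] for c in planted_names])  # (n_triads, 3)
    means = totals[:, None] * comp

    triad_ids = [f"triad{i:05d}" for i in range(config.n_triads)]
    triad_map = pd.DataFrame(
        {
            "triad_id": triad_ids,
            "gene_A": [f"{t}_A" for t in triad_ids],
            "gene_B": [f"{t}_B" for t in triad_ids],
            "gene_D": [f"{t}_D" for t in triad_ids],
        }
    )
    gene_ids = np.array(
        [g for t in triad_ids for g in (f"{t}_A", f"{t}_B", f"{t}_D")]
    )

    samples = [
        _sample_meta_for(cross, stage, rep)
        for cross in config.cross_pair
        for stage in config.stages
        for rep in range(1, config.n_replicates + 1)
    ]
    # scale TPM-space means to expected read counts at the configured depth,
    # so shot noise reflects sequencing depth and the dispersion->0 limit is
    # genuinely noise-free
    total_tpm = means.sum()
    count_scale = config.library_size / total_tpm if total_tpm > 0 else 0.0
    columns = {}
    for s in samples:
        counts = _negative_binomial(rng, means * count_scale, config.nb_dispersion)
        flat = counts.reshape(-1).astype(float)
        total = flat.sum()
        columns[s.sample_id] = flat / total * 1e6 if total > 0 else flat
    values = pd.DataFrame(columns, index=gene_ids)
    expr = ExpressionMatrix(values, samples)
    truth = TruthLabels(triad_category=dict(zip(triad_ids, planted_names)))
    return expr, triad_map, truth


def simulate_allele_counts(config: SimulationConfig):
    """Simulate maternal/paternal allele counts for both cross directions.

    Per gene, direction, stage and replicate: total reads ~
    Poisson(ase_depth_mean); maternal reads ~ Binomial(total, p) with p the
    tissue dosage expectation (0.5 embryo, 2/3 endosperm) for unimprinted
    genes, ``imprint_strength`` for MEGs and ``1 − imprint_strength`` for
    PEGs, in both directions. Returns ``(counts, TruthLabels)``.
    """
    rng = config._child_seed(2)
    n = config.n_genes_ase
    n_meg = int(round(config.frac_meg * n))
    n_peg = int(round(config.frac_peg * n))
    gene_ids = np.array([f"ase{i:05d}" for i in range(n)])
    status = np.array(["not_imprinted"] * n, dtype=object)
    status[:n_meg] = "MEG"
    status[n_meg : n_meg + n_peg] = "PEG"
    rng.shuffle(status)

    rows = []
    for cross in config.cross_pair:
        for stage in config.stages:
            tissue = tissue_for_stage(stage)
            base = 0.5 if tissue == "embryo" else 2.0 / 3.0
            p = np.where(
                status == "MEG",
                config.imprint_strength,
                np.where(status == "PEG", 1.0 - config.imprint_strength, base),
            )
            for rep in range(1, config.n_replicates + 1):
                total = rng.poisson(config.ase_depth_mean, size=n)
                maternal = rng.binomial(total, p)
                rows.append(
                    pd.DataFrame(
                        {
                            "gene_id": gene_ids,
                            "cross": cross,
                            "stage": stage,
                            "tissue": tissue,
                            "replicate": rep,
                            "maternal_reads": maternal,
                            "paternal_reads": total - maternal,
                        }
                    )
                )
    counts = pd.concat(rows, ignore_index=True)
    truth = TruthLabels(imprinting_status=dict(zip(gene_ids, status)))
    return counts, truth


def simulate_isoform_quants(config: SimulationConfig):
    """Simulate isoform quantifications for two groups with planted PSI shifts.

    Genes carry 2–4 isoforms with baseline PSI from a symmetric Dirichlet.
    For ``n_das_isoforms`` isoforms (one per gene), group 2's PSI is shifted
    up by ``delta_psi_planted`` (the gene's other isoforms are renormalized);
    a shift that would push PSI above 1 is clipped with a warning and the
    realized shift recorded. Per-replicate isoform TPM = gene TPM × PSI ×
    lognormal noise. Returns ``(quants_group1, quants_group2, tx2gene,
    TruthLabels)`` where each group is a list of per-replicate DataFrames in
    :func:`polycross.io_formats.read_transcript_quant` layout.
    """
    rng = config._child_seed(3)
    n_genes = config.n_isoform_genes
    iso_counts = rng.integers(2, 5, size=n_genes)
    gene_ids = [f"sgene{i:05d}" for i in range(n_genes)]
    gene_tpm = rng.gamma(
        config.gamma_shape, config.splicing_gene_tpm_mean / config.gamma_shape, size=n_genes
    )
    # keep every gene expressed above the default PSI floor
    gene_tpm = np.maximum(gene_tpm, 2.0)

    records = []
    for g, (gid, k) in enumerate(zip(gene_ids, iso_counts)):
        base = rng.dirichlet(np.full(k, 1.5))
        for j in range(k):
            records.append(
                {
                    "gene_id": gid,
                    "isoform_id": f"{gid}.t{j + 1}",
                    "gene_index": g,
                    "psi1": base[j],
                }
            )
    iso = pd.DataFrame(records)
    iso["psi2"] = iso["psi1"]

    if config.n_das_isoforms > n_genes:
        raise ValidationError("n_das_isoforms cannot exceed n_isoform_genes (one shift per gene)")
    shifted_genes = rng.choice(n_genes, size=config.n_das_isoforms, replace=False)
    planted: dict[str, float] = {}
    for g in shifted_genes:
        block = iso.index[iso["gene_index"] == g]
        # shift the least-included isoform upward to minimize clipping
        target = block[np.argmin(iso.loc[block, "psi1"].to_numpy())]
        old = iso.at[target, "psi1"]
        new = old + config.delta_psi_planted
        if new > 1.0:
            warnings.warn(
                f"planted shift clipped for {iso.at[target, 'isoform_id']}", stacklevel=2
            )
            new = 1.0
        others = block.difference([target])
        rest_old = iso.loc[others, "psi1"].to_numpy()
        scale = (1.0 - new) / rest_old.sum() if rest_old.sum() > 0 else 0.0
        iso.loc[others, "psi2"] = rest_old * scale
        iso.at[target, "psi2"] = new
        planted[iso.at[target, "isoform_id"]] = new - old

    lengths = rng.uniform(500, 3000, size=len(iso))
    eff_lengths = np.maximum(lengths - 200.0, 10.0)
    tx2gene = iso[["isoform_id", "gene_id"]].rename(columns={"isoform_id": "transcript_id"})

    def _group_tables(psi_col: str, group_label: str) -> list[pd.DataFrame]:
        tables = []
        base_tpm = gene_tpm[iso["gene_index"].to_numpy()] * iso[psi_col].to_numpy()
        for rep in range(1, config.n_replicates + 1):
            if config.psi_noise_sigma > 0:
                noise = rng.lognormal(0.0, config.psi_noise_sigma, size=len(iso))
            else:
                noise = np.ones(len(iso))
            tpm = base_tpm * noise
            tables.append(
                pd.DataFrame(
                    {
                        "transcript_id": iso["isoform_id"],
                        "gene_id": iso["gene_id"],
                        "length": lengths,
                        "effective_length": eff_lengths,
                        "tpm": tpm,
                        "num_reads": tpm * eff_lengths / 1000.0,
                        "sample_id": f"{group_label}_r{rep}",
                    }
                )
            )
        return tables

    group1 = _group_tables("psi1", "g1")
    group2 = _group_tables("psi2", "g2")
    truth = TruthLabels(isoform_delta_psi=planted)
    return group1, group2, tx2gene, truth
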