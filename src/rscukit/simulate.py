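"""Synthetic codon-usage studies with known ground truth.

Generates everything the pipeline consumes: CDS FASTA with controllable
per-family codon preferences, healthy/disease gene sets with a planted RSCU
shift, log-normal TPM tables with strain/stage/batch structure, metadata,
and a pseudogene blacklist.  Each synthetic sample is later weighted by
both gene sets, so the "tissue state" of a weighted profile (healthy vs
disease) is known by construction, as are the shifted codons and the batch
of every sample.

The defaults describe a modest bulk-RNA-seq study: 40 genes per set with a
mean CDS length of 300 codons, moderately biased baseline codon preferences
(Dirichlet concentration 8), an RSCU shift of 0.4 planted in six two-fold
degenerate codons, log-normal expression (mu=3, sigma=1 on the natural-log
scale) and an additive log-scale batch shift of 0.5 between two archive
batches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import CODONS, GeneticCode, count_codons, standard_genetic_code

#: Six target codons, one per two-fold family, used for the planted shift.
DEFAULT_TARGET_CODONS = ("AAC", "GAC", "TGC", "CAC", "TTC", "TAC")


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic codon-usage study."""

    seed: int = 0
    n_genes_per_set: int = 40
    n_pseudogenes: int = 4
    mean_cds_codons: int = 300
    cds_codon_spread: int = 100  # uniform half-width around the mean
    dirichlet_concentration: float = 8.0
    rscu_shift: float = 0.4
    target_codons: tuple[str, ...] = DEFAULT_TARGET_CODONS
    strains: tuple[str, ...] = ("C57BL/6",)
    tissue: str = "liver"
    stages: tuple[int, ...] = tuple(range(10, 19))
    samples_per_cell: int = 2  # per strain x stage
    log_tpm_mu: float = 3.0
    log_tpm_sigma: float = 1.0
    stage_effect: float = 0.1  # log-TPM slope per stage for stage-tracking genes
    batch_labels: tuple[str, ...] = ("SRR", "ERR")
    batch_shift: float = 0.5  # additive shift on log-TPM
    normalize_usage: bool = True


@dataclass
class GroundTruth:
    """What the generator planted, for validating downstream recovery."""

    target_codons: tuple[str, ...]
    affected_codons: tuple[str, ...]  # every codon of a shifted family
    batch_of_sample: dict[str, str]
    stage_of_sample: dict[str, int]
    healthy_genes: tuple[str, ...]
    disease_genes: tuple[str, ...]
    pseudogenes: tuple[str, ...]

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


def uniform_preferences(code: GeneticCode) -> dict[str, dict[str, float]]:
    """Equal preference for every codon within each synonymous family."""
    return {
        aa: {c: 1.0 / len(fam) for c in fam} for aa, fam in code.families.items()
    }


def dirichlet_preferences(
    code: GeneticCode, concentration: float, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Random per-family preferences ~ Dirichlet(concentration * uniform)."""
    prefs = {}
    for aa, fam in code.families.items():
        k = len(fam)
        p = rng.dirichlet(np.full(k, concentration / k))
        prefs[aa] = dict(zip(fam, p))
    return prefs


def shift_preferences(
    base: dict[str, dict[str, float]],
    target_codons,
    delta: float,
    code: GeneticCode,
) -> dict[str, dict[str, float]]:
    """Reweight family preferences so targets' expected RSCU rises by delta.

    For a codon with preference p in a family of size k the expected RSCU
    is k*p, so the target preference becomes p + delta/k; the rest of the
    family is scaled down proportionally.  Requests pushing the target RSCU
    above the family size (probability >= 1) are rejected.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    prefs = {aa: dict(fam) for aa, fam in base.items()}
    by_aa: dict[str, list[str]] = {}
    for codon in target_codons:
        aa = code.codon_to_aa.get(codon)
        if aa in (None, "*"):
            raise ValueError(f"{codon!r} is not a sense codon")
        by_aa.setdefault(aa, []).append(codon)
    for aa, targets in by_aa.items():
        fam = prefs[aa]
        k = len(fam)
        if len(targets) >= k:
            raise ValueError(f"cannot shift every codon of family {aa}")
        new_targets = {}
        for c in targets:
            p_new = fam[c] + delta / k
            if p_new >= 1.0:
                raise ValueError(
                    f"shift delta={delta} pushes {c} ({aa}) to probability "
                    f"{p_new:.3f} >= 1"
                )
            new_targets[c] = p_new
        rest = [c for c in fam if c not in new_targets]
        rest_old = sum(fam[c] for c in rest)
        rest_new = 1.0 - sum(new_targets.values())
        if rest_new <= 0 or rest_old <= 0:
            raise ValueError(f"family {aa}: no probability mass left to rescale")
        for c in rest:
            fam[c] = fam[c] * rest_new / rest_old
        fam.update(new_targets)
    return prefs


def generate_cds_set(
    preferences: dict[str, dict[str, float]],
    n: int,
    rng: np.random.Generator,
    mean_codons: int = 300,
    spread: int = 100,
    prefix: str = "gene",
) -> dict[str, str]:
    """Generate ``n`` CDS sequences sampled from per-family codon preferences.

    Amino acids are drawn uniformly (Met enforced at position 0) and each
    is realized as a codon sampled from its family's preference simplex.
    Deterministic for a given generator state.
    """
    for aa, fam in preferences.items():
        total = sum(fam.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in fam.values()):
            raise ValueError(f"preferences for {aa} are not a simplex (sum={total})")
    aa_list = sorted(preferences)
    fam_codons, fam_probs = _pref_tables(preferences)
    proteins = _sample_proteins(aa_list, n, rng, mean_codons, spread)
    return {
        f"{prefix}{i + 1:04d}": _encode_protein(aas, u, fam_codons, fam_probs)
        for i, (aas, u) in enumerate(proteins)
    }


def _sample_proteins(
    aa_list, n: int, rng: np.random.Generator, mean_codons: int, spread: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random amino-acid sequences (Met start) with per-position uniforms.

    The uniforms drive codon choice via the inverse CDF of each family's
    preference simplex, so re-encoding the same proteins under different
    preferences is coupled by common random numbers: identical preferences
    give byte-identical sequences, and small preference shifts change only
    the affected families.
    """
    out = []
    for _ in range(n):
        length = int(rng.integers(mean_codons - spread, mean_codons + spread + 1))
        length = max(length, 2)
        aas = np.concatenate(
            [["M"], rng.choice(aa_list, size=length - 1, replace=True)]
        )
        out.append((aas, rng.random(length)))
    return out


def _encode_protein(aas, uniforms, fam_codons, fam_probs) -> str:
    codons = np.empty(len(aas), dtype=object)
    for aa in np.unique(aas):
        pos = np.flatnonzero(aas == aa)
        cum = np.cumsum(fam_probs[aa])
        picks = np.searchsorted(cum, uniforms[pos], side="right")
        picks = np.clip(picks, 0, len(fam_codons[aa]) - 1)
        codons[pos] = [fam_codons[aa][j] for j in picks]
    return "".join(codons)


def _pref_tables(preferences):
    fam_codons = {aa: sorted(preferences[aa]) for aa in preferences}
    fam_probs = {
        aa: np.array([preferences[aa][c] for c in fam_codons[aa]])
        for aa in preferences
    }
    return fam_codons, fam_probs


def write_fasta(genes: dict[str, str], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for gene_id, seq in genes.items():
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class SyntheticStudy:
    """In-memory bundle of one generated study."""

    config: SyntheticConfig
    genes: dict[str, str]
    codon_counts: dict[str, np.ndarray]
    tpm: pd.DataFrame
    metadata: pd.DataFrame
    healthy_genes: tuple[str, ...]
    disease_genes: tuple[str, ...]
    pseudogenes: tuple[str, ...]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every artifact in the formats the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "cds.fasta",
            "tpm": outdir / "tpm.tsv",
            "metadata": outdir / "metadata.tsv",
            "healthy": outdir / "healthy_genes.txt",
            "disease": outdir / "disease_genes.txt",
            "blacklist": outdir / "pseudogenes.txt",
            "truth": outdir / "ground_truth.json",
        }
        write_fasta(self.genes, paths["fasta"])
        self.tpm.to_csv(paths["tpm"], sep="\t", index_label="gene_id")
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        paths["healthy"].write_text("\n".join(self.healthy_genes) + "\n")
        paths["disease"].write_text("\n".join(self.disease_genes) + "\n")
        paths["blacklist"].write_text(
            "# known pseudogenes\n" + "\n".join(self.pseudogenes) + "\n"
        )
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def study_rscu_groups(study: "SyntheticStudy", code: GeneticCode | None = None):
    """Weight every sample by each gene set and return RSCU group matrices.

    Returns ``(rscu_healthy, rscu_disease, strata)`` where the matrices are
    samples x 61 RSCU values (profile ids ``<sample>:<set>``) and strata
    maps profile id -> embryonic stage.  This is the in-memory equivalent
    of the pipeline's weighting + RSCU stages.
    """
    from .rscu import rscu_matrix, rscu_profile
    from .weighting import weighted_codon_usage

    code = code or standard_genetic_code()
    matrices = {}
    strata = {}
    for label, genes in (
        ("healthy", study.healthy_genes),
        ("disease", study.disease_genes),
    ):
        expr = study.tpm.loc[list(genes)]
        profiles = []
        for s in study.metadata["sample_id"]:
            wp = weighted_codon_usage(
                expr[s], study.codon_counts, sample_id=f"{s}:{label}"
            )
            profiles.append(rscu_profile(wp, code))
            strata[wp.sample_id] = study.truth.stage_of_sample[s]
        matrices[label] = rscu_matrix(profiles)
    return matrices["healthy"], matrices["disease"], pd.Series(strata)


def generate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study from a config (deterministic)."""
    cfg = config or SyntheticConfig()
    code = standard_genetic_code()
    rng = np.random.default_rng(cfg.seed)

    base = dirichlet_preferences(code, cfg.dirichlet_concentration, rng)
    # redraw target families whose baseline leaves no room for the planted
    # shift (target preference must stay below 1 after adding delta/k)
    for codon in cfg.target_codons:
        aa = code.codon_to_aa[codon]
        fam = code.families[aa]
        k = len(fam)
        for _ in range(100):
            if all(
                base[aa][c] + cfg.rscu_shift / k <= 0.95
                for c in cfg.target_codons
                if code.codon_to_aa[c] == aa
            ):
                break
            p = rng.dirichlet(np.full(k, cfg.dirichlet_concentration / k))
            base[aa] = dict(zip(fam, p))
        else:
            raise ValueError(f"cannot accommodate shift {cfg.rscu_shift} in {aa}")
    shifted = shift_preferences(base, cfg.target_codons, cfg.rscu_shift, code)

    # Common-random-number coupling: both sets encode the same protein
    # sequences with the same per-position uniforms, so at rscu_shift = 0
    # the disease set reproduces the healthy set exactly (a true null) and
    # divergence is confined to the shifted families and grows with delta.
    aa_list = sorted(base)
    proteins = _sample_proteins(
        aa_list, cfg.n_genes_per_set, rng, cfg.mean_cds_codons, cfg.cds_codon_spread
    )
    h_codons, h_probs = _pref_tables(base)
    d_codons, d_probs = _pref_tables(shifted)
    healthy = {
        f"hg{i + 1:04d}": _encode_protein(aas, u, h_codons, h_probs)
        for i, (aas, u) in enumerate(proteins)
    }
    disease = {
        f"dg{i + 1:04d}": _encode_protein(aas, u, d_codons, d_probs)
        for i, (aas, u) in enumerate(proteins)
    }
    pseudo = generate_cds_set(
        base, cfg.n_pseudogenes, rng, cfg.mean_cds_codons, cfg.cds_codon_spread,
        prefix="pseudo",
    )
    genes = {**healthy, **disease, **pseudo}
    counts = {g: count_codons(s, gene_id=g) for g, s in genes.items()}

    affected = []
    target_families = {code.codon_to_aa[c] for c in cfg.target_codons}
    for aa in sorted(target_families):
        affected.extend(code.families[aa])

    # samples: strains x stages x replicates, batches round-robin
    rows = []
    for strain in cfg.strains:
        for stage in cfg.stages:
            for rep in range(cfg.samples_per_cell):
                i = len(rows)
                batch = cfg.batch_labels[i % len(cfg.batch_labels)]
                rows.append(
                    {
                        "sample_id": f"S{i + 1:03d}",
                        "strain": strain,
                        "tissue": cfg.tissue,
                        "stage": stage,
                        "library_id": f"{batch}{100000 + i}",
                    }
                )
    metadata = pd.DataFrame(rows)

    gene_ids = list(genes)
    n_genes = len(gene_ids)
    # a third of the genes track embryonic stage (log-linear trend)
    stage_genes = rng.choice(n_genes, size=n_genes // 3, replace=False)
    stage_loading = np.zeros(n_genes)
    stage_loading[stage_genes] = rng.normal(0.0, 1.0, size=len(stage_genes))
    mid_stage = float(np.mean(cfg.stages))

    tpm_cols = {}
    for _, row in metadata.iterrows():
        log_tpm = rng.normal(cfg.log_tpm_mu, cfg.log_tpm_sigma, size=n_genes)
        log_tpm += cfg.stage_effect * (row["stage"] - mid_stage) * stage_loading
        batch_idx = cfg.batch_labels.index(row["library_id"][:3])
        log_tpm += cfg.batch_shift * batch_idx
        tpm_cols[row["sample_id"]] = np.exp(log_tpm)
    tpm = pd.DataFrame(tpm_cols, index=gene_ids)

    truth = GroundTruth(
        target_codons=tuple(cfg.target_codons),
        affected_codons=tuple(affected),
        batch_of_sample={
            r["sample_id"]: r["library_id"][:3] for r in rows
        },
        stage_of_sample={r["sample_id"]: int(r["stage"]) for r in rows},
        healthy_genes=tuple(healthy),
        disease_genes=tuple(disease),
        pseudogenes=tuple(pseudo),
    )
    return SyntheticStudy(
        config=cfg,
        genes=genes,
        codon_counts=counts,
        tpm=tpm,
        metadata=metadata,
        healthy_genes=tuple(healthy),
        disease_genes=tuple(disease),
        pseudogenes=tuple(pseudo),
        truth=truth,
    )
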