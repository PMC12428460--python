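"""Seeded generators for every input the pipeline consumes, with planted
ground truth, so the full funnel → motif → expression → qPCR path is
testable offline.

What the generators emulate
---------------------------
* ``gen_interactions`` — database-style extracts: a miRNA→target table,
  a circRNA annotation, and a sponge-edge table in which a configurable
  set of feed-forward loops is planted.  Decoy entities each fail exactly
  one funnel criterion (a miRNA with too few signature targets; a circRNA
  hosted outside the signature; a circRNA whose binding-site total falls
  below the cohort median), so each filter rule is exercised
  independently and the planted motif set is recoverable exactly.
* ``gen_expression`` — a two-grade tumor cohort (defaults: 89 grade 1 and
  19 subtype-called grade 2 samples, the grade 2 cell split 7 recurrent /
  12 not) with log2-scale normal expression, planted per-stratum shifts,
  subtype labels drawn from per-stratum prevalence vectors, and numeric
  covariates tied to a gene's expression through a Gaussian copula so a
  target Spearman correlation is planted in expectation.
* ``gen_ct_table`` — a qPCR panel (default 19 tissues) where assay ΔCt
  values carry planted cross-assay rank correlations via the same copula
  construction, then receive per-tissue technical noise; the reference
  transcript is generated separately and added back so the table holds
  raw Ct cycles.

Expression is generated directly on the log2 scale (no count simulation
followed by variance stabilization) because the pipeline contract
consumes a normalized matrix; this keeps recovery tests analytic and
fast.

Determinism: identical configs (including seed) produce bit-identical
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CircRecord, CtTable, ExpressionDataset, GeneSignature, MirTargetRecord, SpongeRecord
from .errors import ConfigError

#: latent-normal (Pearson) correlation that yields Spearman rho under a
#: Gaussian copula: r = 2 sin(pi * rho_s / 6)
def _latent_r(rho_s: float) -> float:
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


_DEFAULT_PLANTED_FFLS = (
    ("PIM1", ("hsa-miR-16-5p", "hsa-miR-195-5p", "hsa-miR-124-3p")),
    ("CHEK1", ("hsa-miR-16-5p", "hsa-miR-195-5p", "hsa-miR-193b-3p")),
)

# per-(grade, recurrent) sample counts; grade 2 split mirrors the subtyped
# grade 2 cohort (7 recurrent vs 12 not) used in the recovery analyses
_DEFAULT_N_SAMPLES = {
    (1, "no"): 79,
    (1, "yes"): 10,
    (2, "no"): 12,
    (2, "yes"): 7,
}

# additive log2 shifts: each (filter, shift) adds to matching samples, so
# grade 2 sits at FC 2.3 over grade 1 and recurrent grade 2 at a further
# FC 2.95 over not-recurrent grade 2
_DEFAULT_SHIFTS = {
    "PIM1": (
        ({"who_grade": 2}, math.log2(2.3)),
        ({"who_grade": 2, "recurrent": "yes"}, math.log2(2.95)),
    ),
}

# subtype prevalence vectors (A, B, C) per (grade, recurrent) cell; the
# grade 2 vectors reproduce the reported recurrent vs not-recurrent
# pattern (85.7% C vs 25% C); grade 1 shows the same direction, weaker
_DEFAULT_PREVALENCES = {
    (1, "no"): (0.50, 0.35, 0.15),
    (1, "yes"): (0.25, 0.35, 0.40),
    (2, "no"): (0.333, 0.417, 0.25),
    (2, "yes"): (0.0, 0.143, 0.857),
}

# planted Spearman targets: (gene_x, feature_y, rho, stratum filter)
_DEFAULT_CORRELATIONS = (
    ("PIM1", "NF2", -0.47, {"who_grade": 2}),
    ("PIM1", "ki67_index", 0.42, {"who_grade": 2}),
)

# planted cross-assay Spearman targets for the qPCR panel
_DEFAULT_CT_RHOS = {
    ("hsa_circ_0076215", "hsa_circ_0076216"): 0.87,
    ("hsa_circ_0076215", "PIM1"): 0.58,
    ("hsa_circ_0076216", "PIM1"): 0.68,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generators.

    Defaults reproduce the study conditions of the worked analyses:
    a 34-gene signature, 32 miRNAs, the cohort cell sizes above, planted
    fold-changes 2.3 / 2.95, the grade 2 subtype prevalences, and ΔCt
    rank correlations 0.87 / 0.58 / 0.68 over 19 tissues.
    """

    seed: int = 0
    # interaction tables
    n_signature_genes: int = 34
    n_mirnas: int = 32
    n_circ_per_host: int = 2
    min_targets: int = 4
    planted_ffls: tuple = _DEFAULT_PLANTED_FFLS
    min_sites: int = 3          # per planted sponge edge, plus a Poisson draw
    sites_lambda: float = 3.0
    n_offsig_decoys: int = 2    # circRNAs hosted outside the signature
    # expression cohort
    n_samples: dict = field(default_factory=lambda: dict(_DEFAULT_N_SAMPLES))
    expr_noise_sd: float = 0.25  # within-group sd on the log2 scale
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 2.0
    planted_log2_shifts: dict = field(default_factory=lambda: dict(_DEFAULT_SHIFTS))
    subtype_prevalences: dict = field(default_factory=lambda: dict(_DEFAULT_PREVALENCES))
    planted_correlations: tuple = _DEFAULT_CORRELATIONS
    # qPCR panel
    n_tissues: int = 19
    ct_noise_sd: float = 0.25   # cycles of per-assay technical noise
    ct_assays: tuple = ("hsa_circ_0076215", "hsa_circ_0076216", "PIM1")
    ct_rhos: dict = field(default_factory=lambda: dict(_DEFAULT_CT_RHOS))
    dct_mean: float = 10.0      # mean ΔCt of a non-reference assay
    dct_sd: float = 2.0         # biological spread of ΔCt across tissues
    reference_assay: str = "GAPDH"

    def __post_init__(self) -> None:
        hosts = [h for h, _ in self.planted_ffls]
        if len(set(hosts)) != len(hosts):
            raise ConfigError("planted FFL host genes must be distinct")
        if self.min_targets < 1 or self.n_circ_per_host < 1 or self.min_sites < 1:
            raise ConfigError("counts must be positive")
        if self.n_signature_genes < len(hosts) + self.min_targets:
            raise ConfigError(
                "signature too small to pad planted miRNAs to min_targets"
            )
        for cell, count in self.n_samples.items():
            if count < 1:
                raise ConfigError(f"empty stratum requested: {cell}")
        for cell, probs in self.subtype_prevalences.items():
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ConfigError(f"prevalence vector for {cell} must sum to 1")
        for key, rho in self.ct_rhos.items():
            if not (-1.0 < rho < 1.0):
                raise ConfigError(f"planted rho for {key} must lie in (-1, 1)")
        for _, _, rho, _ in self.planted_correlations:
            if not (-1.0 < rho < 1.0):
                raise ConfigError("planted correlations must lie in (-1, 1)")
        if self.n_tissues < 3:
            raise ConfigError("n_tissues must be >= 3")

    def signature(self) -> GeneSignature:
        hosts = [h for h, _ in self.planted_ffls]
        fillers = [f"SIG{i:02d}" for i in range(1, self.n_signature_genes - len(hosts) + 1)]
        return GeneSignature(name="synthetic-signature", genes=tuple(hosts + fillers))


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for recovery checks."""

    motifs: tuple[tuple[str, str, str], ...] = ()       # (circ, miRNA, gene)
    candidate_mirnas: frozenset[str] = frozenset()
    decoy_mirnas: frozenset[str] = frozenset()
    shifts: tuple = ()                                   # (gene, filter, shift)
    correlations: tuple = ()                             # (x, y, rho, filter)
    ct_rhos: tuple = ()                                  # ((a1, a2), rho)


# ---------------------------------------------------------------------------
# Interaction tables with planted feed-forward loops
# ---------------------------------------------------------------------------

def gen_interactions(
    cfg: SimConfig,
) -> tuple[list[MirTargetRecord], list[CircRecord], list[SpongeRecord], GroundTruth]:
    """Generate miRNA→target, circRNA annotation and sponge tables.

    Construction guarantees that the funnel (candidate selection + MBS
    median filter) followed by motif enumeration recovers exactly the
    planted motif set:

    * every planted miRNA gets >= ``min_targets`` distinct signature
      targets including each of its planted host genes;
    * every planted circRNA gets one sponge edge per planted miRNA of
      its host with ``min_sites`` + Poisson(``sites_lambda``) sites;
    * one low-MBS decoy circRNA is added per planted circRNA (single
      edge, one site), so the cohort median always separates planted
      from decoy totals;
    * decoy miRNAs carry ``min_targets - 1`` targets and off-signature
      decoy circRNAs carry a host gene outside the signature.
    """
    rng = np.random.default_rng(cfg.seed)
    signature = cfg.signature()
    hosts = [h for h, _ in cfg.planted_ffls]
    planted_mirnas = sorted({m for _, mirs in cfg.planted_ffls for m in mirs})
    host_set = set(hosts)
    pad_pool = [g for g in signature.genes if g not in host_set]

    targets: list[MirTargetRecord] = []
    for mir in planted_mirnas:
        own_hosts = [h for h, mirs in cfg.planted_ffls if mir in mirs]
        tgt = list(own_hosts)
        need = max(0, cfg.min_targets - len(tgt))
        extra = rng.choice(pad_pool, size=need, replace=False) if need else []
        tgt.extend(str(g) for g in extra)
        for g in tgt:
            targets.append(MirTargetRecord(mirna_id=mir, target_gene=g, evidence="planted"))

    n_decoy_mir = max(0, cfg.n_mirnas - len(planted_mirnas))
    decoy_mirnas = [f"hsa-miR-9{i:03d}-3p" for i in range(n_decoy_mir)]
    for mir in decoy_mirnas:
        n_tgt = cfg.min_targets - 1
        if n_tgt > 0:
            for g in rng.choice(pad_pool, size=min(n_tgt, len(pad_pool)), replace=False):
                targets.append(
                    MirTargetRecord(mirna_id=mir, target_gene=str(g), evidence="decoy")
                )

    circs: list[CircRecord] = []
    sponges: list[SpongeRecord] = []
    motifs: list[tuple[str, str, str]] = []
    next_id = 1

    def _new_circ(host: str, chrom: str) -> CircRecord:
        nonlocal next_id
        start = int(rng.integers(1_000_000, 100_000_000))
        span = int(rng.integers(800, 6000))
        spliced = int(rng.integers(300, 1500))
        rec = CircRecord(
            circ_id=f"hsa_circ_{next_id:07d}",
            host_gene=host,
            chrom=chrom,
            start=start,
            end=start + span,
            spliced_length=spliced,
        )
        next_id += 1
        return rec

    for h_idx, (host, mirs) in enumerate(cfg.planted_ffls):
        chrom = f"chr{h_idx + 1}"
        for _ in range(cfg.n_circ_per_host):
            circ = _new_circ(host, chrom)
            circs.append(circ)
            for mir in sorted(mirs):
                n_sites = cfg.min_sites + int(rng.poisson(cfg.sites_lambda))
                sponges.append(
                    SpongeRecord(
                        circ_id=circ.circ_id, mirna_id=mir,
                        n_sites=n_sites, agoclip_p_bound=1e-12,
                    )
                )
                motifs.append((circ.circ_id, mir, host))
            # the paired low-MBS decoy: same host, one candidate-miRNA edge,
            # a single binding site -> always below the cohort median
            decoy = _new_circ(host, chrom)
            circs.append(decoy)
            sponges.append(
                SpongeRecord(
                    circ_id=decoy.circ_id, mirna_id=sorted(mirs)[0],
                    n_sites=1, agoclip_p_bound=1e-6,
                )
            )

    for i in range(cfg.n_offsig_decoys if planted_mirnas else 0):
        circ = _new_circ(f"OFFSIG{i:02d}", "chr99")
        circs.append(circ)
        sponges.append(
            SpongeRecord(
                circ_id=circ.circ_id, mirna_id=planted_mirnas[0],
                n_sites=cfg.min_sites + 5, agoclip_p_bound=1e-12,
            )
        )

    truth = GroundTruth(
        motifs=tuple(sorted(motifs)),
        candidate_mirnas=frozenset(planted_mirnas),
        decoy_mirnas=frozenset(decoy_mirnas),
    )
    return targets, circs, sponges, truth


# ---------------------------------------------------------------------------
# Expression cohort
# ---------------------------------------------------------------------------

def _matches(ann_row: pd.Series, filt: dict) -> bool:
    return all(ann_row.get(k) == v for k, v in filt.items())


def gen_expression(cfg: SimConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a log2-scale expression matrix with annotated samples.

    Per-gene values are Normal(baseline, ``expr_noise_sd``) plus the sum
    of all planted shifts whose stratum filter matches the sample.
    Subtype labels are drawn from the per-cell prevalence vectors.
    Planted correlations replace the partner feature inside the target
    stratum with a Gaussian-copula transform of the source gene's latent
    noise, hitting the target Spearman rho in expectation; the
    proliferation-index covariate maps through an exponential so it stays
    positive (monotone maps preserve rank correlations).
    """
    rng = np.random.default_rng(cfg.seed)
    cells = sorted(cfg.n_samples.items())
    rows = []
    for (grade, recurrent), count in cells:
        prev = cfg.subtype_prevalences.get((grade, recurrent))
        for _ in range(count):
            subtype = (
                str(rng.choice(["A", "B", "C"], p=np.asarray(prev) / sum(prev)))
                if prev is not None
                else None
            )
            rows.append(
                {
                    "who_grade": grade,
                    "recurrent": recurrent,
                    "meng_subtype": subtype,
                    "chr1p_loss": str(rng.choice(["yes", "no"], p=[0.1 if grade == 1 else 0.4, 0.9 if grade == 1 else 0.6])),
                    "chr22q_loss": str(rng.choice(["yes", "no"], p=[0.2 if grade == 1 else 0.5, 0.8 if grade == 1 else 0.5])),
                    "necrosis": str(rng.choice(["yes", "no"], p=[0.05 if grade == 1 else 0.35, 0.95 if grade == 1 else 0.65])),
                    "ki67_index": math.nan,
                }
            )
    ann = pd.DataFrame(rows, index=[f"S{i:03d}" for i in range(1, len(rows) + 1)])

    genes = list(cfg.signature().genes)
    for _, y, _, _ in cfg.planted_correlations:
        if y != "ki67_index" and y not in genes:
            genes.append(y)

    n = len(ann)
    latent = {}
    baselines = {}
    values = pd.DataFrame(index=genes, columns=ann.index, dtype=float)
    for gene in genes:
        z = rng.standard_normal(n)
        latent[gene] = z
        base = cfg.expr_baseline_mean + cfg.expr_baseline_sd * rng.standard_normal()
        baselines[gene] = base
        vals = base + cfg.expr_noise_sd * z
        for filt, shift in cfg.planted_log2_shifts.get(gene, ()):
            mask = ann.apply(lambda r: _matches(r, filt), axis=1).to_numpy()
            vals = vals + shift * mask
        values.loc[gene] = vals

    # independent ki-67 outside any planted stratum
    ki67_z = rng.standard_normal(n)

    for x_gene, y_feat, rho, filt in cfg.planted_correlations:
        r = _latent_r(rho)
        mask = ann.apply(lambda row: _matches(row, filt), axis=1).to_numpy()
        eps = rng.standard_normal(n)
        zy = r * latent[x_gene] + math.sqrt(1.0 - r * r) * eps
        if y_feat == "ki67_index":
            ki67_z = np.where(mask, zy, ki67_z)
        else:
            base = baselines[y_feat]
            new_vals = base + cfg.expr_noise_sd * zy
            col = values.loc[y_feat].to_numpy()
            values.loc[y_feat] = np.where(mask, new_vals, col)
    ann["ki67_index"] = np.round(np.exp(2.0 + 0.6 * ki67_z), 2)

    ds = ExpressionDataset(values=values, annotation=ann)
    truth = GroundTruth(
        shifts=tuple(
            (g, tuple(sorted(f.items())), s)
            for g, pairs in cfg.planted_log2_shifts.items()
            for f, s in pairs
        ),
        correlations=tuple(
            (x, y, rho, tuple(sorted(f.items())))
            for x, y, rho, f in cfg.planted_correlations
        ),
    )
    return ds, truth


# ---------------------------------------------------------------------------
# qPCR Ct panel
# ---------------------------------------------------------------------------

_TISSUES = (
    "spleen", "adipose", "kidney", "skeletal_muscle", "cervix", "prostate",
    "trachea", "colon", "ovary", "lung", "small_intestine", "astrocytes",
    "thymus", "placenta", "testis", "heart", "esophagus", "bladder", "brain",
    "liver", "pancreas", "stomach", "thyroid", "skin",
)


def gen_ct_table(cfg: SimConfig) -> tuple[CtTable, GroundTruth]:
    """Generate a raw Ct table with planted cross-assay rank correlations.

    Latent ΔCt values per assay come from a multivariate normal whose
    off-diagonal entries are the copula transforms of the planted
    Spearman targets; per-tissue technical noise (``ct_noise_sd``) is
    added, then the independently generated reference Ct is added back so
    the table stores raw cycles.

    The planted rho refers to the observed ΔCt profiles, so the latent
    correlation is pre-compensated for the attenuation the independent
    technical noise would otherwise introduce (factor 1 + q with
    q = (ct_noise_sd / dct_sd)^2).
    """
    rng = np.random.default_rng(cfg.seed)
    assays = list(cfg.ct_assays)
    k = len(assays)
    attenuation = 1.0 + (cfg.ct_noise_sd / cfg.dct_sd) ** 2
    corr = np.eye(k)
    for (a1, a2), rho in cfg.ct_rhos.items():
        if a1 in assays and a2 in assays:
            i, j = assays.index(a1), assays.index(a2)
            r = math.copysign(min(abs(_latent_r(rho)) * attenuation, 0.999), rho)
            corr[i, j] = corr[j, i] = r
    # guard against a non-PSD user-specified target set
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < 1e-10:
        eigvals = np.clip(eigvals, 1e-10, None)
        corr = eigvecs @ np.diag(eigvals) @ eigvecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    chol = np.linalg.cholesky(corr)

    if cfg.n_tissues > len(_TISSUES):
        tissues = [f"tissue{i:02d}" for i in range(1, cfg.n_tissues + 1)]
    else:
        tissues = list(_TISSUES[: cfg.n_tissues])

    z = chol @ rng.standard_normal((k, cfg.n_tissues))
    dct = cfg.dct_mean + cfg.dct_sd * z
    dct = dct + cfg.ct_noise_sd * rng.standard_normal(dct.shape)
    ref_ct = 18.0 + rng.standard_normal(cfg.n_tissues)
    ct = np.vstack([dct + ref_ct, ref_ct])
    ct = np.clip(ct, 1.0, 45.0)
    table = CtTable(
        ct=pd.DataFrame(ct, index=assays + [cfg.reference_assay], columns=tissues),
        reference=cfg.reference_assay,
    )
    truth = GroundTruth(ct_rhos=tuple(sorted((pair, rho) for pair, rho in cfg.ct_rhos.items())))
    return table, truth
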