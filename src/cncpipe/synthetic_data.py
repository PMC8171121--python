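"""Seeded synthetic input bundles with planted ground truth.

Every pipeline stage can be exercised offline: the generator plants
group-shifted features (differential expression), latent-factor correlated
lncRNA/mRNA pairs (co-expression), genomic neighbors straddling the cis
window, transcripts carrying exact miRNA seed sites (ceRNA triads), and a
dense clique in the PPI edge table.  All randomness flows from one seed.

Intensities are generated on the log2 scale and exponentiated for the
linear bundle, so the log-domain t-test assumptions hold by construction.
Planted co-expression uses a shared latent factor ``x = lam * z + eps``
with ``lam = sigma * sqrt(r)`` and residual sd ``sigma * sqrt(1 - r)`` —
the closed-form, variance-preserving loading giving expected Pearson
correlation ``r`` between two features that share ``z``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cerna import MiRNA, reverse_complement
from .io_formats import (
    ExpressionBundle,
    FeatureAnnotation,
    GroupDesign,
    PPIEdgeTable,
)

__all__ = ["SimulationConfig", "SyntheticTruth", "SyntheticBundle", "generate",
           "truth_recovery_report", "StageRecovery"]

CHROM_LENGTH = 10_000_000  # synthetic chromosomes are 10 Mb


@dataclass
class SimulationConfig:
    seed: int
    n_case: int = 4
    n_control: int = 4
    n_lncrna: int = 120
    n_mrna: int = 300
    de_fraction: float = 0.15
    fold_changes: tuple[float, ...] = (2.0, 2.5, 3.0, 4.0)
    log2_noise_sd: float = 0.25
    base_mean: float = 8.0
    base_sd: float = 1.5
    n_coexpr_pairs: int = 10
    target_r: float = 0.95
    cis_gaps: tuple[int, ...] = (50_000, 150_000, 200_000, 250_000)
    cis_window: int = 200_000
    n_mirnas: int = 8
    n_decoy_mirnas: int = 3
    n_triads: int = 5
    transcript_length: int = 300
    mirna_length: int = 22
    n_low_detection: int = 10
    min_detected: int = 4
    ppi_clique_size: int = 5
    ppi_random_edges: int = 60

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 < self.target_r < 1.0:
            raise ValueError("target_r must be in (0, 1)")
        for name in ("n_case", "n_control", "n_lncrna", "n_mrna", "n_coexpr_pairs",
                     "n_mirnas", "n_triads", "n_low_detection"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticTruth:
    de_features: dict[str, tuple[str, float]]  # id -> (direction, true fold)
    coexpr_pairs: list[tuple[str, str]]
    cis_pairs: list[tuple[str, str, int]]  # (lnc, mrna, gap); includes out-of-window plants
    joint_pair: tuple[str, str] | None
    validated_lncs: list[str]  # panel used as the co-expression lncRNA side
    triads: list[tuple[str, str, str]]  # (lnc, mirna name, mrna)
    ppi_module: frozenset[str]
    low_detection_features: list[str]

    @property
    def cis_pairs_in_window(self) -> list[tuple[str, str, int]]:
        return [p for p in self.cis_pairs if p[2] <= 200_000]


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    bundle: ExpressionBundle
    annotations: dict[str, FeatureAnnotation]
    design: GroupDesign
    transcripts: dict[str, str]
    mirnas: list[MiRNA]
    ppi: PPIEdgeTable
    truth: SyntheticTruth

    def manifest(self) -> dict[str, str]:
        """Config echo plus content hashes of every generated artifact."""
        h = lambda s: hashlib.sha256(s.encode()).hexdigest()[:16]
        return {
            "seed": str(self.config.seed),
            "values_sha": h(self.bundle.values.to_csv()),
            "flags_sha": h(self.bundle.flags.to_csv()),
            "transcripts_sha": h("".join(f">{k}{v}" for k, v in sorted(self.transcripts.items()))),
            "ppi_sha": h(str(sorted(self.ppi.edges))),
        }


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def generate(config: SimulationConfig) -> SyntheticBundle:
    """Build a complete input bundle plus its ground truth from one seed."""
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_case + config.n_control
    if config.min_detected > n_samples:
        raise ValueError("min_detected exceeds sample count")

    lnc_ids = [f"lnc_{i:04d}" for i in range(1, config.n_lncrna + 1)]
    mrna_ids = [f"mrna_{i:04d}" for i in range(1, config.n_mrna + 1)]
    feature_ids = lnc_ids + mrna_ids
    sample_ids = [f"case_{i}" for i in range(1, config.n_case + 1)] + [
        f"ctrl_{i}" for i in range(1, config.n_control + 1)
    ]
    design = GroupDesign(
        {s: ("case" if s.startswith("case") else "control") for s in sample_ids}
    )
    case_cols = np.arange(config.n_case)

    # ---- planted differential expression -------------------------------
    n_de_lnc = int(round(config.de_fraction * config.n_lncrna))
    n_de_mrna = int(round(config.de_fraction * config.n_mrna))
    de_lnc = list(rng.choice(lnc_ids, size=n_de_lnc, replace=False))
    de_mrna = list(rng.choice(mrna_ids, size=n_de_mrna, replace=False))
    de_features: dict[str, tuple[str, float]] = {}
    for pool in (de_lnc, de_mrna):
        for i, fid in enumerate(pool):
            direction = "up" if i % 2 == 0 else "down"
            fold = float(rng.choice(config.fold_changes))
            de_features[fid] = (direction, fold)

    # ---- co-expression pairs (non-DE features share a latent factor) ---
    free_lnc = [f for f in lnc_ids if f not in de_features]
    free_mrna = [f for f in mrna_ids if f not in de_features]
    if config.n_coexpr_pairs > min(len(free_lnc), len(free_mrna)):
        raise ValueError("more planted co-expression pairs than free features")
    co_lnc = list(rng.choice(free_lnc, size=config.n_coexpr_pairs, replace=False))
    co_mrna = list(rng.choice(free_mrna, size=config.n_coexpr_pairs, replace=False))
    coexpr_pairs = list(zip(co_lnc, co_mrna))

    # joint pair: DE in the same direction AND correlated AND cis-adjacent
    joint_pair: tuple[str, str] | None = None
    down_lnc = [f for f in de_lnc if de_features[f][0] == "down"]
    down_mrna = [f for f in de_mrna if de_features[f][0] == "down"]
    if down_lnc and down_mrna:
        joint_pair = (down_lnc[0], down_mrna[0])

    # validated-panel lncRNAs: the co-expression lncRNA side.  Contains the
    # joint pair's lncRNA; cis decoys are drawn from outside the panel so
    # the joint pair is the unique CNC/cis overlap by construction.
    up_lnc_all = [f for f in de_lnc if de_features[f][0] == "up"]
    validated_lncs = sorted(set(up_lnc_all[:3] + down_lnc[:3]))

    # ---- log2 intensity matrix ----------------------------------------
    base = rng.normal(config.base_mean, config.base_sd, size=len(feature_ids))
    base = np.clip(base, 4.0, None)  # keep linear intensities comfortably positive
    log2_vals = base[:, None] + rng.normal(
        0.0, config.log2_noise_sd, size=(len(feature_ids), n_samples)
    )
    idx = {f: i for i, f in enumerate(feature_ids)}
    for fid, (direction, fold) in de_features.items():
        shift = np.log2(fold) * (1 if direction == "up" else -1)
        log2_vals[idx[fid], case_cols] += shift
    # variance-preserving latent loading: lam^2 + resid^2 = sigma^2 and
    # lam^2 / sigma^2 = target_r, so pair members keep the global noise sd
    # (planted DE on the same features stays detectable)
    sigma = config.log2_noise_sd
    lam = sigma * np.sqrt(config.target_r)
    resid_sd = sigma * np.sqrt(1.0 - config.target_r)
    pairs_with_latent = list(coexpr_pairs)
    if joint_pair is not None:
        pairs_with_latent.append(joint_pair)
    for lnc, mrna in pairs_with_latent:
        # latent profile centered within each group (so it cannot confound
        # the planted group shift) and standardized to exact sample moments,
        # keeping the sampling spread of the realized pair correlation tight
        # around the closed-form target at small n
        z = rng.normal(0.0, 1.0, size=n_samples)
        z[: config.n_case] -= z[: config.n_case].mean()
        z[config.n_case :] -= z[config.n_case :].mean()
        z /= z.std()
        for fid in (lnc, mrna):
            i = idx[fid]
            log2_vals[i] = base[i] + lam * z + rng.normal(0.0, resid_sd, size=n_samples)
            if fid in de_features:
                direction, fold = de_features[fid]
                shift = np.log2(fold) * (1 if direction == "up" else -1)
                log2_vals[i, case_cols] += shift

    values = pd.DataFrame(
        np.power(2.0, log2_vals), index=feature_ids, columns=sample_ids
    )

    # ---- detection flags ----------------------------------------------
    flags = pd.DataFrame("P", index=feature_ids, columns=sample_ids)
    protected = set(de_features) | {f for p in pairs_with_latent for f in p}
    decoys = [f for f in feature_ids if f not in protected]
    n_low = min(config.n_low_detection, len(decoys))
    low_detection = list(rng.choice(decoys, size=n_low, replace=False))
    n_absent = n_samples - config.min_detected + 1  # guarantees filter removal
    for fid in low_detection:
        cols = rng.choice(n_samples, size=n_absent, replace=False)
        for c in cols:
            flags.iat[idx[fid], int(c)] = "A"
    # sprinkle Marginal flags that still pass the filter
    for fid in rng.choice([f for f in decoys if f not in low_detection],
                          size=min(5, len(decoys)), replace=False):
        flags.iat[idx[fid], 0] = "M"

    bundle = ExpressionBundle(values, flags, scale="linear")

    # ---- genomic annotation and cis plants ----------------------------
    annotations: dict[str, FeatureAnnotation] = {}
    cis_lnc_pool = [f for f in de_lnc
                    if f not in validated_lncs and (joint_pair is None or f != joint_pair[0])]
    cis_mrna_pool = [f for f in de_mrna if joint_pair is None or f != joint_pair[1]]
    n_cis = min(len(config.cis_gaps), len(cis_lnc_pool), len(cis_mrna_pool))
    cis_pairs: list[tuple[str, str, int]] = []
    chrom_no = 1
    feat_len = 1_000
    for k in range(n_cis):
        gap = config.cis_gaps[k]
        lnc, mrna = cis_lnc_pool[k], cis_mrna_pool[k]
        chrom = f"chr{chrom_no}"
        chrom_no += 1
        lnc_start = 1_000_000
        annotations[lnc] = FeatureAnnotation(
            lnc, _symbol(lnc), "lncRNA", chrom, "+", lnc_start, lnc_start + feat_len
        )
        mrna_start = lnc_start + feat_len + gap
        annotations[mrna] = FeatureAnnotation(
            mrna, _symbol(mrna), "mRNA", chrom, "+", mrna_start, mrna_start + feat_len
        )
        cis_pairs.append((lnc, mrna, gap))
    if joint_pair is not None:
        lnc, mrna = joint_pair
        chrom = f"chr{chrom_no}"
        chrom_no += 1
        annotations[lnc] = FeatureAnnotation(
            lnc, _symbol(lnc), "lncRNA", chrom, "+", 1_000_000, 1_001_000
        )
        annotations[mrna] = FeatureAnnotation(
            mrna, _symbol(mrna), "mRNA", chrom, "+", 1_151_000, 1_152_000
        )
        cis_pairs.append((lnc, mrna, 150_000))
    # everything else far apart: one feature per 500 kb slot, 16 per chromosome
    slot = 0
    for fid in feature_ids:
        if fid in annotations:
            continue
        chrom = f"chrU{slot // 16 + 1}"
        start = 200_000 + (slot % 16) * 550_000
        biotype = "lncRNA" if fid.startswith("lnc_") else "mRNA"
        annotations[fid] = FeatureAnnotation(
            fid, _symbol(fid), biotype, chrom, "+" if slot % 2 == 0 else "-",
            start, start + feat_len
        )
        slot += 1

    # ---- miRNAs and seeded transcripts --------------------------------
    mirnas: list[MiRNA] = []
    used_seeds: set[str] = set()
    mir_num = 11
    while len(mirnas) < config.n_mirnas:
        seq = _random_seq(rng, config.mirna_length)
        if seq[1:8] in used_seeds:
            continue
        used_seeds.add(seq[1:8])
        mirnas.append(MiRNA(f"hsa-miR-{mir_num}-5p", seq))
        mir_num += 2
    for j in range(config.n_decoy_mirnas):
        seq = _random_seq(rng, config.mirna_length)
        if seq[1:8] in used_seeds:
            continue
        used_seeds.add(seq[1:8])
        mirnas.append(MiRNA(f"hsa-miR-{4400 + j}-3p", seq))

    transcripts = {fid: _random_seq(rng, config.transcript_length) for fid in feature_ids}

    up_lnc = [f for f in de_lnc if de_features[f][0] == "up"]
    up_mrna = [f for f in de_mrna if de_features[f][0] == "up"]
    triads: list[tuple[str, str, str]] = []
    n_triads = min(config.n_triads, len(up_lnc), len(up_mrna), config.n_mirnas)
    for k in range(n_triads):
        mir = mirnas[k]
        lnc, mrna = up_lnc[k], up_mrna[k]
        site = reverse_complement(mir.sequence[1:8]) + "A"  # exact 8mer target
        for tid, offset in ((lnc, 40 + 10 * k), (mrna, 120 + 10 * k)):
            seq = transcripts[tid]
            transcripts[tid] = seq[:offset] + site + seq[offset + len(site):]
        triads.append((lnc, mir.name, mrna))

    # ---- PPI edge table -----------------------------------------------
    symbols = [_symbol(f) for f in mrna_ids]
    module = [_symbol(f) for f in de_mrna[: config.ppi_clique_size]]
    edges: list[tuple[str, str, float]] = []
    for i in range(len(module)):
        for j in range(i + 1, len(module)):
            edges.append((module[i], module[j], 0.9))
    others = [s for s in symbols if s not in set(module)]
    for _ in range(config.ppi_random_edges):
        a, b = rng.choice(len(others), size=2, replace=False)
        edges.append((others[int(a)], others[int(b)], float(np.round(rng.uniform(0.4, 0.99), 3))))
    ppi = PPIEdgeTable(edges)

    truth = SyntheticTruth(
        de_features=de_features,
        coexpr_pairs=coexpr_pairs,
        cis_pairs=cis_pairs,
        joint_pair=joint_pair,
        validated_lncs=validated_lncs,
        triads=triads,
        ppi_module=frozenset(module),
        low_detection_features=low_detection,
    )
    return SyntheticBundle(config, bundle, annotations, design, transcripts, mirnas, ppi, truth)


def _symbol(feature_id: str) -> str:
    kind, num = feature_id.split("_")
    return f"{'LNC' if kind == 'lnc' else 'GENE'}{num}"


# ---------------------------------------------------------------------------
# recovery reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageRecovery:
    stage: str
    n_truth: int
    n_called: int
    n_recovered: int
    n_extra: int

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_truth if self.n_truth else 1.0

    @property
    def precision(self) -> float:
        return self.n_recovered / self.n_called if self.n_called else 1.0


def truth_recovery_report(
    truth: SyntheticTruth,
    de_called: Sequence[str] = (),
    cnc_called: Sequence[tuple[str, str]] = (),
    cis_called: Sequence[tuple[str, str]] = (),
    overlap_called: Sequence[tuple[str, str]] = (),
    cerna_called: Sequence[tuple[str, str, str]] = (),
) -> dict[str, StageRecovery]:
    """Per-stage recall of planted items and count of non-planted calls."""
    report: dict[str, StageRecovery] = {}

    def _stage(name, truth_set, called):
        called = set(called)
        recovered = truth_set & called
        report[name] = StageRecovery(
            name, len(truth_set), len(called), len(recovered), len(called - truth_set)
        )

    _stage("de", set(truth.de_features), de_called)
    _stage("cnc", set(truth.coexpr_pairs), cnc_called)
    _stage("cis", {(l, m) for l, m, _ in truth.cis_pairs_in_window}, cis_called)
    _stage("overlap", {truth.joint_pair} if truth.joint_pair else set(), overlap_called)
    _stage("cerna", set(truth.triads), cerna_called)
    return report
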