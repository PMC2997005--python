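"""Synthetic study generator with planted ground truth.

Emulates the full input side of the analysis so every pipeline stage is
testable without external downloads:

* a qPCR Ct table over 10 samples in three gestational periods (3/5/2
  samples), with an endogenous-control row, Gaussian Ct noise, and
  undetermined wells;
* probe-level mRNA intensities over a second 3/1/2-sample period scheme,
  with multi-probe genes;
* two target-prediction files, one per database dialect, carrying every
  planted (microRNA, gene) suppression pair in both files plus decoy pairs
  split between the files.

The planted signal: Group I microRNAs gain abundance (Ct falls by
``effect_size_log2`` cycles per period step, so RQ rises 2^effect-fold),
Group II lose it, Group III stay flat. Genes of planted pairs receive
period profiles that are a decreasing affine function of their microRNA's
noise-free RQ profile, so the per-period Pearson correlation tends to -1 as
noise goes to 0. Unlinked (decoy and background) genes carry no
developmental trend: their per-period means follow a random walk whose step
size defaults to the intensity noise scale, vanishing in the noise-free
limit.

All randomness flows from explicit seeds; identical parameters and seeds
give byte-identical output files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .periods import Period, PeriodScheme
from .qpcr import CtMatrix, DEFAULT_UNDETERMINED_THRESHOLD

__all__ = [
    "GroundTruth",
    "default_mirna_scheme",
    "default_mrna_scheme",
    "generate_truth",
    "generate_ct_table",
    "generate_mrna_table",
    "generate_prediction_files",
    "simulate_study",
    "SimulatedStudy",
]

CONTROL_ID = "RNU48"
CONTROL_CT = 20.0

DEFAULT_GROUP_FRACTIONS = (0.02, 0.17, 0.81)  # echoes the observed 4/35/173 split
DEFAULT_N_MIRNAS = 212
DEFAULT_N_GENES = 500
DEFAULT_PROBES_PER_GENE = 2
DEFAULT_N_PLANTED = 40
DEFAULT_N_DECOYS = 60
DEFAULT_EFFECT_LOG2 = 2.0   # cycles per period step
DEFAULT_CT_NOISE_SD = 0.3   # cycles
DEFAULT_INTENSITY_CV = 0.05  # fractional noise on hybridization intensity
BASELINE_CT_RANGE = (23.0, 29.0)


def default_mirna_scheme() -> PeriodScheme:
    """Three gestational periods of 3/5/2 samples with the 2/4/2 quorum."""
    return PeriodScheme(
        [
            Period("10-11wga", ("S01", "S02", "S03"), min_detected=2),
            Period("13-15wga", ("S04", "S05", "S06", "S07", "S08"), min_detected=4),
            Period("21-22wga", ("S09", "S10"), min_detected=2),
        ]
    )


def default_mrna_scheme() -> PeriodScheme:
    """The mRNA array periods: 9-11 / 15 / 20-23 wga with 3/1/2 samples."""
    return PeriodScheme(
        [
            Period("9-11wga", ("A01", "A02", "A03"), min_detected=1),
            Period("15wga", ("A04",), min_detected=1),
            Period("20-23wga", ("A05", "A06"), min_detected=1),
        ]
    )


@dataclass
class GroundTruth:
    """Planted configuration of one synthetic study."""

    group_of_mirna: dict[str, str]             # miRNA -> I / II / III
    planted_pairs: frozenset[tuple[str, str]]  # true suppression pairs
    decoy_pairs: frozenset[tuple[str, str]]    # predicted but unlinked
    gene_ids: tuple[str, ...]
    seed: int
    ct_noise_sd: float = DEFAULT_CT_NOISE_SD
    intensity_noise_sd: float = DEFAULT_INTENSITY_CV

    def __post_init__(self) -> None:
        if self.planted_pairs & self.decoy_pairs:
            raise ValueError("planted and decoy pairs overlap")
        for mirna, _ in self.planted_pairs:
            if self.group_of_mirna.get(mirna) not in ("I", "II"):
                raise ValueError(
                    f"planted pair uses {mirna!r} which is not in group I/II"
                )

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.group_of_mirna)

    @property
    def planted_genes(self) -> set[str]:
        return {g for _, g in self.planted_pairs}

    def mirnas_in(self, *groups: str) -> list[str]:
        return [m for m, g in self.group_of_mirna.items() if g in groups]


def generate_truth(
    n_mirnas: int = DEFAULT_N_MIRNAS,
    n_genes: int = DEFAULT_N_GENES,
    group_fractions: tuple[float, float, float] = DEFAULT_GROUP_FRACTIONS,
    n_planted_pairs: int = DEFAULT_N_PLANTED,
    n_decoys: int = DEFAULT_N_DECOYS,
    seed: int = 0,
) -> GroundTruth:
    """Draw a reproducible planted configuration.

    Group sizes follow ``group_fractions`` (I, II, III) up to rounding.
    Each planted pair links a distinct gene to a Group I or II microRNA;
    decoy pairs only use genes that carry no planted signal, so a decoy's
    profile is genuinely unlinked from its microRNA.
    """
    if abs(sum(group_fractions) - 1.0) > 1e-9:
        raise ValueError("group fractions must sum to 1")
    if min(group_fractions) < 0:
        raise ValueError("group fractions must be non-negative")
    rng = np.random.default_rng(seed)
    n_one = int(round(n_mirnas * group_fractions[0]))
    n_two = int(round(n_mirnas * group_fractions[1]))
    if n_one + n_two > n_mirnas:
        raise ValueError("infeasible group fractions")
    mirnas = [f"miR-{1000 + i}" for i in range(n_mirnas)]
    groups = ["I"] * n_one + ["II"] * n_two + ["III"] * (n_mirnas - n_one - n_two)
    group_of = dict(zip(mirnas, groups))

    genes = tuple(f"GENE{i:04d}" for i in range(n_genes))
    changing = [m for m in mirnas if group_of[m] in ("I", "II")]
    if n_planted_pairs > 0 and not changing:
        raise ValueError("no group I/II microRNAs available for planted pairs")
    if n_planted_pairs > n_genes:
        raise ValueError("more planted pairs than genes")
    planted_genes = rng.choice(n_genes, size=n_planted_pairs, replace=False)
    planted = frozenset(
        (changing[int(rng.integers(len(changing)))], genes[int(g)])
        for g in planted_genes
    ) if n_planted_pairs else frozenset()

    free_genes = [g for g in genes if g not in {ge for _, ge in planted}]
    max_decoys = len(free_genes) * len(mirnas)
    if n_decoys > max_decoys:
        raise ValueError("infeasible decoy count")
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < n_decoys:
        mirna = mirnas[int(rng.integers(n_mirnas))]
        gene = free_genes[int(rng.integers(len(free_genes)))]
        decoys.add((mirna, gene))
    return GroundTruth(
        group_of_mirna=group_of,
        planted_pairs=planted,
        decoy_pairs=frozenset(decoys),
        gene_ids=genes,
        seed=seed,
    )


def _trend_sign(group: str) -> int:
    """Sign of the log2-RQ slope over periods: +1 for group I, -1 for II."""
    return {"I": 1, "II": -1, "III": 0}[group]


def true_rq_shape(group: str, effect_size_log2: float, n_periods: int = 3) -> np.ndarray:
    """Noise-free relative RQ profile over periods (affine-equivalent form).

    Group I: 2^(0, e, 2e); Group II: 2^(0, -e, -2e); Group III: flat. The
    absolute RQ scale of a microRNA multiplies this shape and cancels in
    any Pearson correlation.
    """
    steps = np.arange(n_periods, dtype=float)
    return np.exp2(_trend_sign(group) * effect_size_log2 * steps)


def generate_ct_table(
    truth: GroundTruth,
    scheme: PeriodScheme | None = None,
    baseline_ct_range: tuple[float, float] = BASELINE_CT_RANGE,
    effect_size_log2: float = DEFAULT_EFFECT_LOG2,
    ct_noise_sd: float = DEFAULT_CT_NOISE_SD,
    dropout_rate: float = 0.0,
    undetermined_threshold: float = DEFAULT_UNDETERMINED_THRESHOLD,
    seed: int = 0,
) -> CtMatrix:
    """Simulate the qPCR card: Ct per (microRNA, sample) plus the control row.

    Group I microRNAs lose ``effect_size_log2`` cycles per period step
    (abundance rises), Group II gain them, Group III stay at their baseline;
    every cell receives independent Gaussian noise of ``ct_noise_sd``
    cycles. Cells that land at or above the undetermined threshold, plus a
    ``dropout_rate`` fraction of random wells, become undetermined. The
    control row is constant up to noise and never drops out.
    """
    scheme = scheme or default_mirna_scheme()
    rng = np.random.default_rng(seed)
    mirnas = truth.mirna_ids
    samples = scheme.samples
    step_of_sample = np.array(
        [i for i, period in enumerate(scheme) for _ in period.samples], dtype=float
    )
    baseline = rng.uniform(*baseline_ct_range, size=len(mirnas))
    slope = np.array(
        [-_trend_sign(truth.group_of_mirna[m]) * effect_size_log2 for m in mirnas]
    )
    clean = baseline[:, None] + slope[:, None] * step_of_sample[None, :]
    noisy = clean + rng.normal(0.0, ct_noise_sd, size=clean.shape)
    control = CONTROL_CT + rng.normal(0.0, ct_noise_sd, size=len(samples))

    if dropout_rate > 0:
        dropped = rng.random(size=noisy.shape) < dropout_rate
        noisy = np.where(dropped, undetermined_threshold, noisy)
    noisy = np.clip(noisy, 0.0, None)
    ct = pd.DataFrame(noisy, index=mirnas, columns=samples)
    ct.loc[CONTROL_ID] = np.clip(control, 0.0, None)
    ct = ct.mask(ct >= undetermined_threshold)
    return CtMatrix(ct=ct, control_id=CONTROL_ID)


def generate_mrna_table(
    truth: GroundTruth,
    mrna_scheme: PeriodScheme | None = None,
    probes_per_gene: int = DEFAULT_PROBES_PER_GENE,
    intensity_noise_sd: float = DEFAULT_INTENSITY_CV,
    background_walk_sd: float | None = None,
    effect_size_log2: float = DEFAULT_EFFECT_LOG2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the probe-level mRNA array and its probe-to-gene map.

    Genes in planted pairs get per-period means that decrease affinely in
    their microRNA's noise-free RQ shape (per-period Pearson r of -1 at
    zero noise). Unlinked genes get a per-period random walk with step
    s.d. ``background_walk_sd`` (defaults to the intensity noise level, so
    background genes go flat in the noise-free limit). Each gene is
    expanded to ``probes_per_gene`` probes with independent multiplicative
    Gaussian noise of fractional s.d. ``intensity_noise_sd``.

    ``effect_size_log2`` must match the value used for the Ct table so the
    planted anti-parallel shapes correspond.
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    mrna_scheme = mrna_scheme or default_mrna_scheme()
    if background_walk_sd is None:
        background_walk_sd = intensity_noise_sd
    rng = np.random.default_rng(seed)
    n_periods = len(mrna_scheme)
    genes = list(truth.gene_ids)
    mirna_of_gene = {g: m for m, g in truth.planted_pairs}

    baseline = rng.lognormal(mean=np.log(500.0), sigma=0.5, size=len(genes))
    period_values = np.empty((len(genes), n_periods))
    for i, gene in enumerate(genes):
        if gene in mirna_of_gene:
            group = truth.group_of_mirna[mirna_of_gene[gene]]
            shape = true_rq_shape(group, effect_size_log2, n_periods)
            z = shape / shape.max()  # in (0, 1]
            period_values[i] = baseline[i] * (1.6 - 1.2 * z)
        else:
            steps = rng.normal(0.0, background_walk_sd, size=n_periods)
            steps[0] = 0.0
            walk = np.cumsum(steps)
            period_values[i] = baseline[i] * np.exp(walk)

    samples = mrna_scheme.samples
    period_index = [i for i, period in enumerate(mrna_scheme) for _ in period.samples]
    rows = {}
    probe_rows = []
    for i, gene in enumerate(genes):
        per_sample = period_values[i][period_index]
        for p in range(probes_per_gene):
            probe_id = f"{gene}_p{p + 1}"
            noise = rng.normal(0.0, intensity_noise_sd, size=len(samples))
            rows[probe_id] = np.clip(per_sample * (1.0 + noise), 0.0, None)
            probe_rows.append({"probe_id": probe_id, "gene_id": gene})
    probe_matrix = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    probe_matrix.index.name = "probe_id"
    probe_map = pd.DataFrame(probe_rows)
    return probe_matrix, probe_map


def _targetscan_rows(pairs, rng) -> list[dict]:
    rows = []
    for mirna, gene in pairs:
        n_sites = int(rng.integers(1, 3))
        for s in range(n_sites):
            start = int(rng.integers(100, 2000))
            rows.append(
                {
                    "Gene ID": f"GID:{gene}",
                    "Gene Symbol": gene,
                    "Transcript ID": f"NM_{zlib.crc32(gene.encode()) % 900000:06d}",
                    "Species ID": "9606",
                    "miRNA": f"hsa-{mirna}",
                    "Site Type": str(int(rng.integers(1, 4))),
                    "UTR start": str(start),
                    "UTR end": str(start + 7),
                    "context score": f"{-rng.uniform(0.05, 0.6):.3f}",
                    "context percentile": str(int(rng.integers(1, 100))),
                }
            )
    return rows


def _mirbase_rows(pairs, rng) -> list[dict]:
    rows = []
    for mirna, gene in pairs:
        n_transcripts = int(rng.integers(1, 3))
        for t in range(n_transcripts):
            rows.append(
                {
                    "GROUP": "miRNA_target",
                    "SEQ": f"hsa-{mirna}",
                    "METHOD": "miranda",
                    "FEATURE": "miRNA_target",
                    "CHR": str(int(rng.integers(1, 23))),
                    "START": str(int(rng.integers(1_000, 1_000_000))),
                    "END": str(int(rng.integers(1_000_000, 2_000_000))),
                    "STRAND": "+" if rng.random() < 0.5 else "-",
                    "PHASE": ".",
                    "SCORE": f"{rng.uniform(14, 20):.4f}",
                    "PVALUE_OG": f"{rng.uniform(0, 0.05):.6f}",
                    "TRANSCRIPT_ID": f"ENST{zlib.crc32(f'{gene}/{t}'.encode()) % 10 ** 11:011d}",
                    "EXTERNAL_NAME": gene if t % 2 == 0 else gene.lower(),
                }
            )
    return rows


def generate_prediction_files(
    truth: GroundTruth,
    mirbase_path,
    targetscan_path,
    seed: int = 0,
) -> tuple[Path, Path]:
    """Write the two prediction dumps covering planted and decoy pairs.

    Every planted pair appears in both files (so the intersection scope can
    recover all of them); decoy pairs are split round-robin among
    miRBase-only, TargetScan-only and both-files. Rows are written in a
    seeded shuffled order, with per-pair site/transcript multiplicity, mixed
    gene-symbol case in the miRBase dump, and a handful of non-human decoy
    rows in the TargetScan dump to exercise the species filter.
    """
    rng = np.random.default_rng(seed)
    planted = sorted(truth.planted_pairs)
    decoys = sorted(truth.decoy_pairs)
    mirbase_pairs = list(planted)
    targetscan_pairs = list(planted)
    for i, pair in enumerate(decoys):
        if i % 3 == 0:
            mirbase_pairs.append(pair)
        elif i % 3 == 1:
            targetscan_pairs.append(pair)
        else:
            mirbase_pairs.append(pair)
            targetscan_pairs.append(pair)

    ts_rows = _targetscan_rows(targetscan_pairs, rng)
    # non-human rows that the default species filter must drop
    for mirna, gene in targetscan_pairs[:3]:
        ts_rows.append(
            {
                "Gene ID": f"GID:{gene}",
                "Gene Symbol": gene,
                "Transcript ID": "XM_000001",
                "Species ID": "10090",
                "miRNA": f"mmu-{mirna}",
                "Site Type": "1",
                "UTR start": "10",
                "UTR end": "17",
                "context score": "-0.100",
                "context percentile": "50",
            }
        )
    mb_rows = _mirbase_rows(mirbase_pairs, rng)
    rng.shuffle(ts_rows)
    rng.shuffle(mb_rows)

    targetscan_path = Path(targetscan_path)
    mirbase_path = Path(mirbase_path)
    pd.DataFrame(ts_rows).to_csv(targetscan_path, sep="\t", index=False)
    pd.DataFrame(mb_rows).to_csv(mirbase_path, sep="\t", index=False)
    return mirbase_path, targetscan_path


@dataclass
class SimulatedStudy:
    """All inputs of one synthetic study plus its ground truth."""

    truth: GroundTruth
    ct: CtMatrix
    mirna_scheme: PeriodScheme
    probe_matrix: pd.DataFrame
    probe_map: pd.DataFrame
    mrna_scheme: PeriodScheme
    mirbase_file: Path | None = None
    targetscan_file: Path | None = None
    params: dict = field(default_factory=dict)


def simulate_study(
    seed: int = 0,
    out_dir=None,
    n_mirnas: int = DEFAULT_N_MIRNAS,
    n_genes: int = DEFAULT_N_GENES,
    group_fractions: tuple[float, float, float] = DEFAULT_GROUP_FRACTIONS,
    n_planted_pairs: int = DEFAULT_N_PLANTED,
    n_decoys: int = DEFAULT_N_DECOYS,
    effect_size_log2: float = DEFAULT_EFFECT_LOG2,
    ct_noise_sd: float = DEFAULT_CT_NOISE_SD,
    intensity_noise_sd: float = DEFAULT_INTENSITY_CV,
    background_walk_sd: float | None = None,
    probes_per_gene: int = DEFAULT_PROBES_PER_GENE,
    dropout_rate: float = 0.0,
) -> SimulatedStudy:
    """Generate one complete synthetic study (optionally writing its files).

    Child seeds for each generator stage derive deterministically from
    ``seed``. When ``out_dir`` is given, the Ct table, probe table, probe
    map, both prediction dumps and a ground-truth JSON are written there.
    """
    from .qpcr import write_ct_table

    seeds = np.random.SeedSequence(seed).spawn(4)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    truth = generate_truth(
        n_mirnas=n_mirnas,
        n_genes=n_genes,
        group_fractions=group_fractions,
        n_planted_pairs=n_planted_pairs,
        n_decoys=n_decoys,
        seed=child[0],
    )
    truth.ct_noise_sd = ct_noise_sd
    truth.intensity_noise_sd = intensity_noise_sd
    mirna_scheme = default_mirna_scheme()
    mrna_scheme = default_mrna_scheme()
    ct = generate_ct_table(
        truth,
        scheme=mirna_scheme,
        effect_size_log2=effect_size_log2,
        ct_noise_sd=ct_noise_sd,
        dropout_rate=dropout_rate,
        seed=child[1],
    )
    probe_matrix, probe_map = generate_mrna_table(
        truth,
        mrna_scheme=mrna_scheme,
        probes_per_gene=probes_per_gene,
        intensity_noise_sd=intensity_noise_sd,
        background_walk_sd=background_walk_sd,
        effect_size_log2=effect_size_log2,
        seed=child[2],
    )
    study = SimulatedStudy(
        truth=truth,
        ct=ct,
        mirna_scheme=mirna_scheme,
        probe_matrix=probe_matrix,
        probe_map=probe_map,
        mrna_scheme=mrna_scheme,
        params={
            "seed": seed,
            "effect_size_log2": effect_size_log2,
            "ct_noise_sd": ct_noise_sd,
            "intensity_noise_sd": intensity_noise_sd,
            "dropout_rate": dropout_rate,
            "probes_per_gene": probes_per_gene,
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_ct_table(ct, out_dir / "ct_table.tsv")
        probe_matrix.to_csv(out_dir / "probe_intensities.tsv", sep="\t", float_format="%.6f")
        probe_map.to_csv(out_dir / "probe_map.tsv", sep="\t", index=False)
        study.mirbase_file, study.targetscan_file = generate_prediction_files(
            truth,
            out_dir / "mirbase_targets_v5.txt",
            out_dir / "targetscan_context_scores.txt",
            seed=child[3],
        )
        _write_truth_json(truth, out_dir / "ground_truth.json")
    else:
        import tempfile

        tmp = Path(tempfile.mkdtemp(prefix="pancmir_sim_"))
        study.mirbase_file, study.targetscan_file = generate_prediction_files(
            truth,
            tmp / "mirbase_targets_v5.txt",
            tmp / "targetscan_context_scores.txt",
            seed=child[3],
        )
    return study


def _write_truth_json(truth: GroundTruth, path) -> None:
    import json

    payload = {
        "seed": truth.seed,
        "group_of_mirna": truth.group_of_mirna,
        "planted_pairs": sorted(map(list, truth.planted_pairs)),
        "decoy_pairs": sorted(map(list, truth.decoy_pairs)),
        "ct_noise_sd": truth.ct_noise_sd,
        "intensity_noise_sd": truth.intensity_noise_sd,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
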