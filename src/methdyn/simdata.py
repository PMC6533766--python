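"""Synthetic cohorts and bisulfite reads emulating a glucocorticoid
challenge study.

Two repeated-measures designs are templated: a small deep time course
(n=19; blood draws at 0, 1, 3, 6 and 23 h after dexamethasone) and a larger
validation cohort (n=89; 0, 3 and ~18 h).  Per-CpG true methylation is

    level = clamp(pi0 + u_subject + g * delta(t)/100 + covariate terms + eps,
                  0.001, 0.999)

with a subject random intercept ``u ~ N(0, subject_sd/100)``, a per-site
time profile ``delta(t)`` in percentage points (``delta(0) = 0``) peaking at
3-6 h and decaying toward baseline by ~23 h, a genotype moderation
multiplier ``g`` applied to risk-allele (CT/TT) carriers, mean-centred
covariate slopes and occasion-level noise ``eps ~ N(0, residual_sd/100)``.
Effects are additive on the proportion scale, matching how deltas are
reported (percentage points, not logits).

Reads are simulated per molecule: CpG methylation is Bernoulli(level),
non-CpG cytosines are unmethylated (blood non-CpG methylation is
negligible, which is what makes the CHH-based conversion-rate QC work),
bisulfite conversion of unmethylated cytosines succeeds with probability
``conversion_rate``, and sequencing error substitutes any base uniformly
with probability ``seq_error``.  Mate 1 covers the amplicon 5' end, mate 2
the 3' end (reverse-complemented), overlapping when 2*read_length exceeds
the amplicon length.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import Amplicon, AmpliconPanel, reverse_complement

__all__ = [
    "SimulationConfig",
    "CohortDemographics",
    "TruthTensor",
    "simulate_cohort",
    "simulate_reads",
    "expected_apparent_level",
    "delta_shape",
    "default_site_effects",
    "study1_config",
    "study2_config",
    "make_toy_panel",
    "write_reference",
]

# canonical response shape: fraction of the peak delta realised at each hour
DELTA_SHAPE_ANCHORS = ((0.0, 0.0), (1.0, 0.4), (3.0, 0.8), (6.0, 1.0), (23.0, 0.2))

# DEX-induced lymphopenia: multiplicative profile on the baseline count
_LYMPH_ANCHORS = ((0.0, 1.0), (1.0, 0.85), (3.0, 0.55), (6.0, 0.5), (23.0, 0.95))


def delta_shape(t: float) -> float:
    """Fraction of the peak methylation delta realised ``t`` hours post-dose."""
    xs = np.array([a[0] for a in DELTA_SHAPE_ANCHORS])
    ys = np.array([a[1] for a in DELTA_SHAPE_ANCHORS])
    return float(np.interp(t, xs, ys))


def _lymph_profile(t: float) -> float:
    xs = np.array([a[0] for a in _LYMPH_ANCHORS])
    ys = np.array([a[1] for a in _LYMPH_ANCHORS])
    return float(np.interp(t, xs, ys))


@dataclass(frozen=True)
class CohortDemographics:
    """Marginal distributions used to draw subject-level covariates."""

    n_male: int
    n_female: int
    age_mean: float
    age_sd: float
    bmi_mean: float = 25.0
    bmi_sd: float = 3.5
    smoking_mean: float = 0.0
    smoking_sd: float = 1.0
    n_cases: int = 0
    lymph_mean: float = 2.0
    lymph_sd: float = 0.4


@dataclass
class SimulationConfig:
    """All generative parameters of one synthetic cohort."""

    n_subjects: int
    timepoints_h: tuple[float, ...]
    genotype_freqs: dict[str, float]
    baseline_level: dict[str, float]
    delta_profile: dict[str, dict[float, float]]
    genotype_interaction: dict[str, float] = field(default_factory=dict)
    subject_sd: float = 3.0  # percentage points
    residual_sd: float = 1.5  # percentage points, occasion-level
    covariate_effects: dict[str, float] = field(default_factory=dict)
    conversion_rate: float = 0.995
    seq_error: float = 0.002
    coverage_mean: float = 1000.0
    read_length: int = 150
    seed: int = 0
    demographics: CohortDemographics = field(
        default_factory=lambda: CohortDemographics(19, 0, 25.4, 2.9)
    )

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        for nm, v in (
            ("conversion_rate", self.conversion_rate),
            ("seq_error", self.seq_error),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1], got {v}")
        tot = sum(self.genotype_freqs.get(g, 0.0) for g in ("CC", "CT", "TT"))
        if abs(tot - 1.0) > 1e-8:
            raise ValueError(f"genotype_freqs must sum to 1, got {tot}")
        for site, p in self.baseline_level.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"baseline level of {site} not in [0,1]: {p}")
        for site, prof in self.delta_profile.items():
            if abs(prof.get(0.0, 0.0)) > 1e-12:
                raise ValueError(f"delta_profile of {site} must have delta(0)=0")

    @property
    def sites(self) -> list[str]:
        return list(self.baseline_level)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class TruthTensor:
    """True methylation proportions, subject x site x time, plus the design."""

    levels: np.ndarray  # (n_subjects, n_sites, n_times)
    subjects: list[str]
    sites: list[str]
    times: list[float]
    sample_sheet: pd.DataFrame

    def level(self, subject: str, site: str, time_h: float) -> float:
        return float(
            self.levels[
                self.subjects.index(subject),
                self.sites.index(site),
                self.times.index(time_h),
            ]
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, subj in enumerate(self.subjects):
            for j, site in enumerate(self.sites):
                for k, t in enumerate(self.times):
                    rows.append((subj, site, t, self.levels[i, j, k]))
        return pd.DataFrame(rows, columns=["subject_id", "cpg_id", "time_h", "level"])

    def write_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def _exact_allocation(n: int, freqs: dict[str, float], order: tuple[str, ...]) -> list[str]:
    """Allocate n items to categories matching freqs as closely as possible
    (largest-remainder rounding); deterministic."""
    raw = {g: n * freqs.get(g, 0.0) for g in order}
    counts = {g: int(np.floor(v)) for g, v in raw.items()}
    rem = n - sum(counts.values())
    frac = sorted(order, key=lambda g: (-(raw[g] - counts[g]), g))
    for g in frac[:rem]:
        counts[g] += 1
    out: list[str] = []
    for g in order:
        out.extend([g] * counts[g])
    return out


def simulate_cohort(cfg: SimulationConfig) -> TruthTensor:
    """Draw a full cohort: design, covariates and true methylation levels."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, times, sites = cfg.n_subjects, list(cfg.timepoints_h), cfg.sites
    d = cfg.demographics

    subjects = [f"subj{i + 1:03d}" for i in range(n)]
    genotypes = np.array(_exact_allocation(n, cfg.genotype_freqs, ("CC", "CT", "TT")))
    rng.shuffle(genotypes)
    n_f = min(d.n_female, n)
    sexes = np.array(["M"] * (n - n_f) + ["F"] * n_f)
    rng.shuffle(sexes)
    cases = np.array(["case"] * min(d.n_cases, n) + ["control"] * max(0, n - d.n_cases))
    rng.shuffle(cases)
    age = rng.normal(d.age_mean, d.age_sd, n).round(1)
    bmi = rng.normal(d.bmi_mean, d.bmi_sd, n).round(1)
    smoking = rng.normal(d.smoking_mean, d.smoking_sd, n).round(2)
    lymph0 = np.clip(rng.normal(d.lymph_mean, d.lymph_sd, n), 0.3, None)

    rows = []
    lymph = np.empty((n, len(times)))
    for k, t in enumerate(times):
        lymph[:, k] = np.clip(
            lymph0 * _lymph_profile(t) + rng.normal(0.0, 0.08, n), 0.1, None
        )
    for i, subj in enumerate(subjects):
        for k, t in enumerate(times):
            rows.append(
                (
                    f"{subj}_t{t:g}",
                    subj,
                    t,
                    genotypes[i],
                    age[i],
                    sexes[i],
                    bmi[i],
                    smoking[i],
                    cases[i],
                    round(lymph[i, k], 3),
                )
            )
    sheet = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "subject_id",
            "time_h",
            "genotype",
            "age",
            "sex",
            "BMI",
            "smoking_score",
            "case_status",
            "lymphocyte_count",
        ],
    )

    # covariate design matrix per subject x time, mean-centred so that pi0
    # stays the cohort-mean baseline
    cov_values = {
        "age": np.repeat(age[:, None], len(times), axis=1),
        "sex": np.repeat((sexes == "F").astype(float)[:, None], len(times), axis=1),
        "BMI": np.repeat(bmi[:, None], len(times), axis=1),
        "smoking_score": np.repeat(smoking[:, None], len(times), axis=1),
        "case_status": np.repeat((cases == "case").astype(float)[:, None], len(times), axis=1),
        "lymphocyte_count": lymph,
    }

    u = rng.normal(0.0, cfg.subject_sd / 100.0, n)
    carrier = np.isin(genotypes, ("CT", "TT"))
    levels = np.empty((n, len(sites), len(times)))
    for j, site in enumerate(sites):
        pi0 = cfg.baseline_level[site]
        prof = cfg.delta_profile.get(site, {})
        gmult = cfg.genotype_interaction.get(site, 1.0)
        g = np.where(carrier, gmult, 1.0)
        for k, t in enumerate(times):
            delta = prof.get(t, 0.0) / 100.0
            mean = pi0 + u + g * delta
            for cov, slope in cfg.covariate_effects.items():
                x = cov_values[cov]
                mean = mean + slope * (x[:, k] - x.mean())
            eps = rng.normal(0.0, cfg.residual_sd / 100.0, n)
            levels[:, j, k] = np.clip(mean + eps, 0.001, 0.999)

    return TruthTensor(levels, subjects, sites, times, sheet)


def expected_apparent_level(level: float, c: float, e: float) -> float:
    """Closed-form apparent methylation after conversion failure and
    sequencing error; used as an oracle for the read simulator and caller.

    A molecule emits C if methylated or if conversion of its unmethylated C
    failed; sequencing error then substitutes uniformly among the other
    three bases, so a true C is called C with probability 1-e and a true T
    is miscalled C with probability e/3 (and vice versa).
    """
    for nm, v in (("level", level), ("c", c), ("e", e)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{nm} must be in [0,1]")
    p_c = level + (1.0 - level) * (1.0 - c)
    call_c = p_c * (1.0 - e) + (1.0 - p_c) * e / 3.0
    call_t = (1.0 - p_c) * (1.0 - e) + p_c * e / 3.0
    return call_c / (call_c + call_t)


_A, _C, _G, _T = 0, 1, 2, 3
_BASE_CODE = {"A": _A, "C": _C, "G": _G, "T": _T}
_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_CODE = np.array([_T, _G, _C, _A], dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE[b] for b in seq], dtype=np.uint8)


def _rows_to_strings(codes: np.ndarray) -> list[str]:
    ascii_rows = _CODE_BASE[codes]
    return [r.tobytes().decode("ascii") for r in ascii_rows]


def _open_deterministic_gz(path):
    """gzip writer with zeroed mtime so identical content is byte-identical."""
    raw = open(path, "wb")
    return gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)


def simulate_reads(
    truth: TruthTensor,
    panel: AmpliconPanel,
    cfg: SimulationConfig,
    outdir,
) -> dict[str, tuple[str, str]]:
    """Write paired gzip FASTQ per sample; returns sample_id -> (R1, R2).

    Read names encode sample, amplicon and molecule index so that
    assignment accuracy can be audited against the truth.
    """
    import os

    cfg.validate()
    os.makedirs(outdir, exist_ok=True)
    for a in panel:
        if cfg.read_length > a.length:
            raise ValueError(
                f"read_length {cfg.read_length} exceeds amplicon {a.name!r} "
                f"length {a.length}"
            )

    site_index = {s: j for j, s in enumerate(truth.sites)}
    # per amplicon: encoded sequence, cytosine offsets and their truth rows
    amp_prep = []
    for a in panel:
        codes = _encode(a.sequence)
        cyt_base = _C if a.template_strand == "top" else _G
        conv_base = _T if a.template_strand == "top" else _A
        offsets, truth_rows = [], []
        for s in panel.amplicon_sites(a.name):
            off = s.template_pos - a.start
            offsets.append(off)
            truth_rows.append(site_index.get(s.cpg_id, -1) if s.context == "CpG" else -1)
        amp_prep.append(
            (a, codes, np.array(offsets, dtype=int), np.array(truth_rows, dtype=int),
             cyt_base, conv_base)
        )

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xFA57]))
    out: dict[str, tuple[str, str]] = {}
    L = cfg.read_length
    for row in truth.sample_sheet.itertuples(index=False):
        sample = row.sample_id
        i_subj = truth.subjects.index(row.subject_id)
        k_time = truth.times.index(row.time_h)
        p1 = os.path.join(outdir, f"{sample}_R1.fastq.gz")
        p2 = os.path.join(outdir, f"{sample}_R2.fastq.gz")
        with _open_deterministic_gz(p1) as f1, _open_deterministic_gz(p2) as f2:
            for a, codes, offs, trows, cyt_base, conv_base in amp_prep:
                n_mol = int(rng.poisson(cfg.coverage_mean))
                if n_mol == 0:
                    continue
                mols = np.tile(codes, (n_mol, 1))
                if offs.size:
                    lv = np.zeros(offs.size)
                    cpg_mask = trows >= 0
                    lv[cpg_mask] = truth.levels[i_subj, trows[cpg_mask], k_time]
                    meth = rng.random((n_mol, offs.size)) < lv[None, :]
                    converted = rng.random((n_mol, offs.size)) < cfg.conversion_rate
                    mols[:, offs] = np.where(
                        meth | ~converted, cyt_base, conv_base
                    ).astype(np.uint8)
                if cfg.seq_error > 0:
                    err = rng.random(mols.shape) < cfg.seq_error
                    n_err = int(err.sum())
                    if n_err:
                        shift = rng.integers(1, 4, n_err).astype(np.uint8)
                        mols[err] = (mols[err] + shift) % 4
                r1 = mols[:, :L]
                r2 = _COMP_CODE[mols[:, -L:]][:, ::-1]
                q1 = np.clip(rng.normal(37.0, 2.5, r1.shape), 2, 40).astype(np.uint8)
                q2 = np.clip(rng.normal(37.0, 2.5, r2.shape), 2, 40).astype(np.uint8)
                s1, s2 = _rows_to_strings(r1), _rows_to_strings(r2)
                qs1 = [(q + 33).tobytes().decode("ascii") for q in q1]
                qs2 = [(q + 33).tobytes().decode("ascii") for q in q2]
                for m in range(n_mol):
                    name = f"{sample}|{a.name}|{m}"
                    f1.write(f"@{name}/1\n{s1[m]}\n+\n{qs1[m]}\n".encode())
                    f2.write(f"@{name}/2\n{s2[m]}\n+\n{qs2[m]}\n".encode())
        out[sample] = (p1, p2)
    return out


def counts_from_truth(
    truth: TruthTensor,
    coverage: float = 1000.0,
    conversion_rate: float = 1.0,
    seq_error: float = 0.0,
    seed: int = 0,
):
    """Sample a methylation call matrix directly from true levels.

    Skips the read level entirely: per cell, coverage ~ Poisson and
    methylated calls ~ Binomial(coverage, apparent level).  Useful for
    exercising the longitudinal statistics at realistic measurement noise
    without simulating and processing FASTQ.
    """
    from .bsproc import MethCallMatrix

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0DE]))
    rows = []
    for i, subj in enumerate(truth.subjects):
        for k, t in enumerate(truth.times):
            sample = f"{subj}_t{t:g}"
            for j, site in enumerate(truth.sites):
                cov = max(1, int(rng.poisson(coverage)))
                p = expected_apparent_level(
                    float(truth.levels[i, j, k]), conversion_rate, seq_error
                )
                meth = int(rng.binomial(cov, p))
                rows.append((site, "CpG", "sim", sample, meth, cov - meth, 0))
    df = pd.DataFrame(rows, columns=MethCallMatrix.COLUMNS)
    return MethCallMatrix(df)


def default_site_effects(
    cpg_ids: list[str],
    timepoints_h: tuple[float, ...],
    n_dmc: int,
    rng: np.random.Generator,
    delta_max_range: tuple[float, float] = (-17.0, -1.0),
    baseline_range: tuple[float, float] = (0.10, 0.90),
    frac_hyper: float = 0.26,
) -> tuple[dict[str, float], dict[str, dict[float, float]], list[str]]:
    """Assign baselines and response profiles to a site list.

    The first ``n_dmc`` sites (after shuffling) respond to the challenge
    with a peak delta drawn from ``delta_max_range`` (percentage points;
    a minority, ``frac_hyper``, flip sign to hypermethylation, matching the
    ~74%-demethylation split seen in vivo); the rest are null.  Returns
    (baseline_level, delta_profile, true_dmc_ids).
    """
    ids = list(cpg_ids)
    order = rng.permutation(len(ids))
    dmc_ids = [ids[i] for i in order[:n_dmc]]
    baseline = {
        s: float(rng.uniform(*baseline_range)) for s in ids
    }
    profile: dict[str, dict[float, float]] = {}
    for s in ids:
        if s in dmc_ids:
            dmax = float(rng.uniform(*delta_max_range))
            if rng.random() < frac_hyper:
                dmax = -dmax
            profile[s] = {t: dmax * delta_shape(t) for t in timepoints_h}
        else:
            profile[s] = {t: 0.0 for t in timepoints_h}
    return baseline, profile, dmc_ids


def study1_config(
    baseline_level: dict[str, float],
    delta_profile: dict[str, dict[float, float]],
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Deep time course: n=19 men, draws at 0/1/3/6/23 h, genotype 6 CC /
    6 CT / 7 TT."""
    kw = dict(
        n_subjects=19,
        timepoints_h=(0.0, 1.0, 3.0, 6.0, 23.0),
        genotype_freqs={"CC": 6 / 19, "CT": 6 / 19, "TT": 7 / 19},
        baseline_level=baseline_level,
        delta_profile=delta_profile,
        seed=seed,
        demographics=CohortDemographics(
            n_male=19, n_female=0, age_mean=25.4, age_sd=2.9
        ),
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def study2_config(
    baseline_level: dict[str, float],
    delta_profile: dict[str, dict[float, float]],
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Validation cohort: n=89, draws at 0/3/~18 h, genotype 50 CC / 30 CT /
    9 TT, mixed sex, 59 depressed in-patients."""
    kw = dict(
        n_subjects=89,
        timepoints_h=(0.0, 3.0, 18.0),
        genotype_freqs={"CC": 50 / 89, "CT": 30 / 89, "TT": 9 / 89},
        baseline_level=baseline_level,
        delta_profile=delta_profile,
        seed=seed,
        demographics=CohortDemographics(
            n_male=67,
            n_female=22,
            age_mean=41.6,
            age_sd=14.0,
            bmi_mean=25.1,
            bmi_sd=3.8,
            smoking_mean=-0.6,
            smoking_sd=4.9,
            n_cases=59,
        ),
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def make_toy_panel(
    n_amplicons: int = 3,
    length: int = 240,
    gap: int = 30,
    chrom: str = "chr6S",
    seed: int = 0,
    alternate_strands: bool = True,
) -> tuple[AmpliconPanel, str]:
    """Generate a small random panel on one synthetic contig.

    Returns the panel and the contig sequence (for writing a FASTA).  Base
    composition is CG-rich enough to yield a handful of CpGs and many CHH
    sites per amplicon.
    """
    rng = np.random.default_rng(seed)
    total = n_amplicons * length + (n_amplicons + 1) * gap
    contig = "".join(
        rng.choice(list("ACGT"), total, p=[0.28, 0.24, 0.24, 0.24])
    )
    amplicons = []
    flanks = {}
    pos = gap
    for i in range(n_amplicons):
        start, end = pos + 1, pos + length
        strand = "bottom" if (alternate_strands and i % 2 == 1) else "top"
        name = f"PCR{i + 1:02d}"
        amplicons.append(
            Amplicon(name, chrom, start, end, strand, contig[start - 1 : end])
        )
        flanks[name] = (contig[start - 3 : start - 1], contig[end : end + 2])
        pos = end + gap
    return AmpliconPanel(amplicons, flanks), contig


def write_reference(contig_seq: str, chrom: str, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(contig_seq), width):
            fh.write(contig_seq[i : i + width] + "\n")
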