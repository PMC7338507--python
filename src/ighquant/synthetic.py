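"""Synthetic data generators: spliced reads over a toy multi-class locus and
simulated cohorts with known proportional-hazards effects.

Every generator is deterministic given (config, seed) and emits its ground
truth alongside the data, so the quantifier, the cohort statistics and the
survival models can all be tested end-to-end without any external download.

Read simulation
    A toy chromosome carries several antibody "classes", each a transcript of
    equally sized exons separated by introns.  Reads are placed uniformly
    along a class's transcript and spliced back to genomic coordinates,
    yielding M/N CIGARs; soft clips and small indels are injected at
    configurable rates, a decoy region absorbs off-locus reads, and MAPQ is
    drawn from a high/low mixture so the quality filter is exercised.  The
    per-class ground-truth base counts are computed during generation by a
    per-position brute-force walk that is independent of the quantifier's
    CIGAR arithmetic.

Cohort simulation
    Clinical covariates are drawn with configurable prevalences (receptor
    status derives from a simulated staining percentage with the >10% cell
    positivity rule), Ig expression is multivariate normal with a block
    correlation structure (the IGHG1-4 and IGHA1-2 blocks strongly
    co-expressed, moderate cross-block correlation), and survival times
    follow an exponential proportional-hazards model with independent
    exponential censoring calibrated to a target event fraction.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .locus import GenomicInterval, LocusModel, merge_intervals
from .quantify import AlignmentRecord, parse_cigar
from .stats import GeneSetCollection

SIM_CHROM = "chr14"
DECOY_GAP = 100_000  # bases between the last class and the decoy region


def config_hash(cfg) -> str:
    """Short stable hash of a dataclass config, for output provenance."""
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Locus + read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSimConfig:
    n_classes: int = 3
    exons_per_class: int = 3
    exon_length: int = 300
    intron_length: int = 800
    class_gap: int = 5_000
    class_reads: dict[str, int] = field(default_factory=dict)  # default 200 each
    read_length: int = 50
    splice_prob: float = 1.0  # reads may span exon junctions when placed there
    softclip_prob: float = 0.1
    indel_prob: float = 0.05
    decoy_fraction: float = 0.3
    low_mapq_frac: float = 0.1
    high_mapq: int = 60
    low_mapq_max: int = 10  # low component drawn uniform in [0, low_mapq_max]
    overlap_pair: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.splice_prob, self.softclip_prob, self.indel_prob,
                  self.decoy_fraction, self.low_mapq_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReadSimConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def class_names(n: int) -> list[str]:
    base = ["IGHM", "IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1", "IGHA2", "IGHE"]
    if n <= len(base):
        return base[:n]
    return base + [f"IGHX{i}" for i in range(n - len(base))]


def simulate_locus(config: ReadSimConfig) -> tuple[LocusModel, dict[str, list[GenomicInterval]]]:
    """Build a toy locus: per-class exon layouts laid out left to right.

    Returns the LocusModel (merged intervals) and the per-class transcript
    layout (exons in transcript order) used to splice simulated reads.  With
    ``overlap_pair`` the second class additionally shares the first class's
    first exon, giving exactly one degenerate shared interval for edge-case
    tests.
    """
    names = class_names(config.n_classes)
    layouts: dict[str, list[GenomicInterval]] = {}
    cursor = 10_000
    for name in names:
        exons = []
        for _ in range(config.exons_per_class):
            exons.append(GenomicInterval(SIM_CHROM, cursor, cursor + config.exon_length))
            cursor += config.exon_length + config.intron_length
        cursor += config.class_gap
        layouts[name] = exons
    if config.overlap_pair and len(names) >= 2:
        layouts[names[1]] = [layouts[names[0]][0]] + layouts[names[1]]
    classes = {name: merge_intervals(exons) for name, exons in layouts.items()}
    return LocusModel(classes=classes), layouts


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated alignment, ready to serialize as a SAM line."""

    name: str
    chrom: str
    pos: int  # 0-based
    mapq: int
    cigar: str

    def to_record(self) -> AlignmentRecord:
        return AlignmentRecord(
            chrom=self.chrom, pos=self.pos, mapq=self.mapq,
            cigar=tuple(parse_cigar(self.cigar)),
        )

    def to_sam_line(self) -> str:
        ops = parse_cigar(self.cigar)
        qlen = sum(n for op, n in ops if op in "MIS=X")
        seq = "A" * qlen
        return "\t".join([
            self.name, "0", self.chrom, str(self.pos + 1), str(self.mapq),
            self.cigar, "*", "0", "0", seq, "*",
        ])


def brute_force_bases(pos: int, cigar: str, intervals: Sequence[GenomicInterval],
                      chrom: str = SIM_CHROM) -> int:
    """Reference implementation: walk the CIGAR one base at a time.

    Counts aligned read bases (M/=/X) whose reference position lies in any
    interval.  Used as the generation-time ground truth, independent of the
    quantifier's segment-overlap arithmetic.
    """
    positions = {p for iv in intervals if iv.chrom == chrom
                 for p in range(iv.start, iv.end)}
    ref = pos
    count = 0
    for op, length in parse_cigar(cigar):
        if op in "M=X":
            for _ in range(length):
                if ref in positions:
                    count += 1
                ref += 1
        elif op in "DN":
            ref += length
    return count


def _transcript_to_genomic(layout: Sequence[GenomicInterval], tpos: int, span: int
                           ) -> tuple[int, str]:
    """Map a transcript window [tpos, tpos+span) to (genomic pos, M/N CIGAR)."""
    blocks: list[tuple[int, int]] = []  # genomic (start, end) per exon piece
    remaining = span
    offset = tpos
    for exon in layout:
        elen = len(exon)
        if offset >= elen:
            offset -= elen
            continue
        take = min(elen - offset, remaining)
        blocks.append((exon.start + offset, exon.start + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    if remaining > 0:
        raise ValueError("read window extends past transcript end")
    cigar = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            gap = s - blocks[i - 1][1]
            if gap > 0:
                cigar.append(f"{gap}N")
        cigar.append(f"{e - s}M")
    return blocks[0][0], "".join(cigar)


def simulate_reads(
    model: LocusModel,
    layouts: dict[str, list[GenomicInterval]],
    config: ReadSimConfig,
    mapq_min: int = 10,
) -> tuple[list[SimulatedRead], dict[str, int]]:
    """Emit simulated reads plus brute-force ground-truth base counts.

    The ground truth applies the same read-selection rules the quantifier
    uses (primary mapped reads with MAPQ strictly above ``mapq_min``) but
    counts overlap by per-position brute force.
    """
    rng = np.random.default_rng(config.seed)
    reads: list[SimulatedRead] = []
    truth = {cls: 0 for cls in model.classes}

    per_class = {cls: config.class_reads.get(cls, 200) for cls in layouts}
    total_class_reads = sum(per_class.values())
    n_decoy = (0 if config.decoy_fraction == 0 else
               int(round(total_class_reads * config.decoy_fraction /
                         max(1e-12, 1.0 - config.decoy_fraction))))
    if config.decoy_fraction >= 1.0:
        per_class = {cls: 0 for cls in per_class}
        n_decoy = max(total_class_reads, 1)

    decoy_start = max(iv.end for ivs in model.classes.values() for iv in ivs) + DECOY_GAP
    idx = 0

    def draw_mapq() -> int:
        if rng.random() < config.low_mapq_frac:
            return int(rng.integers(0, config.low_mapq_max + 1))
        return config.high_mapq

    for cls, n_reads in per_class.items():
        layout = layouts[cls]
        tlen = sum(len(e) for e in layout)
        for _ in range(n_reads):
            span = min(config.read_length, tlen)
            sc = 0
            if rng.random() < config.softclip_prob:
                sc = int(rng.integers(1, max(2, config.read_length // 5)))
                span = max(1, span - sc)
            tpos = int(rng.integers(0, tlen - span + 1))
            pos, cigar = _transcript_to_genomic(layout, tpos, span)
            if rng.random() < config.indel_prob:
                cigar = _inject_indel(cigar, rng)
            if sc:
                cigar = (f"{sc}S{cigar}" if rng.random() < 0.5 else f"{cigar}{sc}S")
            mapq = draw_mapq()
            reads.append(SimulatedRead(f"read{idx}", SIM_CHROM, pos, mapq, cigar))
            idx += 1
    for _ in range(n_decoy):
        pos = decoy_start + int(rng.integers(0, 10_000))
        reads.append(SimulatedRead(
            f"read{idx}", SIM_CHROM, pos, draw_mapq(), f"{config.read_length}M"))
        idx += 1

    for read in reads:
        if read.mapq <= mapq_min:
            continue
        for cls, ivs in model.classes.items():
            truth[cls] += brute_force_bases(read.pos, read.cigar, ivs, read.chrom)
    return reads, truth


def _inject_indel(cigar: str, rng: np.random.Generator) -> str:
    """Split the first M block of length >2 with a 1-2 base I or D."""
    ops = parse_cigar(cigar)
    for i, (op, length) in enumerate(ops):
        if op == "M" and length > 2:
            cut = int(rng.integers(1, length))
            ind_op = "I" if rng.random() < 0.5 else "D"
            ind_len = int(rng.integers(1, 3))
            new = ops[:i] + [("M", cut), (ind_op, ind_len), ("M", length - cut)] + ops[i + 1:]
            return "".join(f"{n}{o}" for o, n in new)
    return cigar


def write_sam(reads: Sequence[SimulatedRead], model: LocusModel, path: str | Path,
              comment: str = "") -> None:
    """Write a minimal plain-text SAM: @HD, @SQ for the toy chromosome, @CO."""
    max_end = max(iv.end for ivs in model.classes.values() for iv in ivs)
    ref_len = max(max_end + DECOY_GAP + 20_000,
                  max((r.pos for r in reads), default=0) + 10_000)
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{SIM_CHROM}\tLN:{ref_len}"]
    if comment:
        lines.append(f"@CO\t{comment}")
    lines.extend(r.to_sam_line() for r in sorted(reads, key=lambda r: (r.pos, r.name)))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Internal-control experiment: counts-per-base vs FPKM on the same reads
# ---------------------------------------------------------------------------


@dataclass
class FpkmControlConfig:
    """Paired quantification of one control gene across samples.

    The control transcript (the J-chain gene) is quantified both by the
    base-allocation route and by an FPKM-style fragment count over the same
    simulated reads; abundance varies ``abundance_range`` across samples
    (default 200-fold) with Poisson read sampling.
    """

    n_samples: int = 60
    # mean reads per sample, 200-fold range; the floor corresponds to a
    # well-detected gene (~1 FPKM at bulk depth), as for the J-chain control
    abundance_range: tuple[float, float] = (50.0, 10_000.0)
    read_length: int = 50
    library_decoys: int = 2000
    exons: int = 4
    exon_length: int = 300
    low_mapq_frac: float = 0.05
    softclip_prob: float = 0.1
    indel_prob: float = 0.05
    poisson: bool = True  # False: deterministic read counts (noiseless coverage)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValueError("control experiment needs >=20 samples")
        lo, hi = self.abundance_range
        if hi / lo < 100:
            raise ValueError("abundance must vary >=100-fold")


def simulate_fpkm_control(config: FpkmControlConfig) -> pd.DataFrame:
    """Per-sample paired (log2 counts-per-base-per-million, log2 FPKM) values.

    Returns a DataFrame with columns ``true_abundance``, ``gene_reads``,
    ``library_reads``, ``log2_cpbm``, ``log2_fpkm``.  Both metrics are
    computed from the same Poisson-sampled reads: the first through the
    base-allocation quantifier, the second as fragments per kilobase of
    transcript per million mapped reads.
    """
    from .quantify import quantify_records  # local import avoids cycle at module load

    rng = np.random.default_rng(config.seed)
    lo, hi = config.abundance_range
    abundances = np.exp(rng.uniform(math.log(lo), math.log(hi), config.n_samples))

    rows = []
    for i, lam in enumerate(abundances):
        cfg = ReadSimConfig(
            n_classes=1, exons_per_class=config.exons,
            exon_length=config.exon_length,
            read_length=config.read_length,
            class_reads={"IGHM": int(rng.poisson(lam)) if config.poisson
                         else int(round(lam))},
            decoy_fraction=0.0,
            low_mapq_frac=config.low_mapq_frac,
            softclip_prob=config.softclip_prob,
            indel_prob=config.indel_prob,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        model, layouts = simulate_locus(cfg)
        reads, _ = simulate_reads(model, layouts, cfg)
        # relabel the single simulated class as the J-chain control gene
        model = LocusModel(classes={"IGJ": model.classes["IGHM"]})
        n_gene = len(reads)
        n_decoy = config.library_decoys + int(rng.integers(-200, 201))
        records = [r.to_record() for r in reads]
        decoy_pos = max(iv.end for iv in model.classes["IGJ"]) + DECOY_GAP
        records.extend(
            AlignmentRecord(SIM_CHROM, decoy_pos, 60,
                            ((("M", config.read_length)),))
            for _ in range(n_decoy)
        )
        n_total = n_gene + n_decoy
        expr = quantify_records(records, model)["IGJ"]
        tlen_kb = model.class_length("IGJ") / 1000.0
        fpkm = n_gene / (tlen_kb * (n_total / 1e6))
        rows.append((lam, n_gene, n_total, expr.value, math.log2(1.0 + fpkm)))
    return pd.DataFrame(
        rows,
        columns=["true_abundance", "gene_reads", "library_reads",
                 "log2_cpbm", "log2_fpkm"],
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

IG_CLASSES = ["IGHM", "IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1", "IGHA2", "IGJ"]


def default_ig_correlation() -> pd.DataFrame:
    """Block correlation: IGHG1-4 and IGHA1-2 blocks high, cross-block moderate."""
    corr = pd.DataFrame(0.4, index=IG_CLASSES, columns=IG_CLASSES)
    for block in (["IGHG1", "IGHG2", "IGHG3", "IGHG4"], ["IGHA1", "IGHA2"]):
        corr.loc[block, block] = 0.85
    corr.loc["IGJ", :] = 0.5
    corr.loc[:, "IGJ"] = 0.5
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class CohortSimConfig:
    """Simulated breast-cancer-like cohort under known hazards.

    Covariate prevalences and effect sizes default to values of the order
    reported for population-based breast cancer series: ~1/3 node-positive
    and >20 mm tumors, predominantly ER-positive disease concentrated in the
    luminal PAM50 subtypes, ~10% HER2 amplification, and a protective Ig
    effect of HR 0.85 per SD with ~10% observed events under heavy censoring.
    """

    n: int = 3000
    seed: int = 0
    node_pos: float = 0.35
    size_gt20: float = 0.35
    chemo_frac: float = 0.40
    endocrine_frac: float = 0.55
    grade_probs: tuple[float, float, float] = (0.20, 0.45, 0.35)
    pam50_probs: dict[str, float] = field(default_factory=lambda: {
        "basal": 0.10, "her2e": 0.10, "lumA": 0.50, "lumB": 0.22, "normal": 0.08})
    er_pos_by_pam50: dict[str, float] = field(default_factory=lambda: {
        "basal": 0.10, "her2e": 0.30, "lumA": 0.98, "lumB": 0.95, "normal": 0.80})
    her2_amp_by_pam50: dict[str, float] = field(default_factory=lambda: {
        "basal": 0.05, "her2e": 0.60, "lumA": 0.05, "lumB": 0.10, "normal": 0.05})
    age_mean: float = 62.0
    age_sd: float = 12.0
    ig_mean: float = 4.0
    ig_sd: float = 1.0
    ig_correlation: pd.DataFrame | None = None
    # log-hazard per SD (Ig) or per level (clinical)
    beta_ig: dict[str, float] = field(default_factory=lambda: {
        c: math.log(0.85) for c in IG_CLASSES})
    beta_clinical: dict[str, float] = field(default_factory=lambda: {
        "node_pos": math.log(1.5), "size_gt20": math.log(1.75),
        "er_pos": math.log(0.55), "her2_amp": math.log(1.3),
        "grade3": math.log(1.6), "age_per_year": 0.02, "chemo": math.log(0.9)})
    baseline_hazard: float = 1.0 / 3650.0  # per day
    event_frac_os: float = 0.10
    event_frac_rfs: float = 0.15
    missing_fraction: float = 0.0
    active_ig: str = "IGHA2"  # the Ig variable whose effect enters the hazard

    def __post_init__(self) -> None:
        if not 0 <= self.event_frac_os < 1 or not 0 <= self.event_frac_rfs < 1:
            raise ValueError("event fractions must be in [0,1)")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0,1)")


def _calibrate_censor_rate(lam: np.ndarray, event_frac: float) -> float:
    """Censoring hazard mu such that mean lam/(lam+mu) equals event_frac.

    With event and censoring times both exponential, subject i is observed
    to fail with probability lam_i/(lam_i+mu); bisect on mu.
    """
    lo, hi = 1e-12, float(lam.max()) * 1e6
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if np.mean(lam / (lam + mid)) > event_frac:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def simulate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw a cohort table plus the true log-hazard vector used to generate it.

    ER/PR positivity is derived from a simulated percentage of stained cells
    with the clinical rule: positive if strictly more than 10% of cells
    stain.  Survival and recurrence times are exponential under the linear
    predictor; censoring is independent exponential, calibrated so the
    expected event fraction matches the config.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    pam_levels = list(config.pam50_probs)
    pam50 = rng.choice(pam_levels, size=n, p=list(config.pam50_probs.values()))
    er_p = np.array([config.er_pos_by_pam50[p] for p in pam50])
    her2_p = np.array([config.her2_amp_by_pam50[p] for p in pam50])
    # staining percentage: high mode for tumors drawn ER-positive, low mode else
    er_high = rng.random(n) < er_p
    er_pct = np.where(er_high, rng.uniform(20, 100, n), rng.uniform(0, 10, n))
    er_pos = er_pct > 10.0
    pr_high = rng.random(n) < np.where(er_pos, 0.8, 0.1)
    pr_pct = np.where(pr_high, rng.uniform(20, 100, n), rng.uniform(0, 10, n))
    pr_pos = pr_pct > 10.0
    her2 = rng.random(n) < her2_p
    node = rng.random(n) < config.node_pos
    size = rng.random(n) < config.size_gt20
    chemo = rng.random(n) < config.chemo_frac
    endo = rng.random(n) < config.endocrine_frac
    grade = rng.choice([1, 2, 3], size=n, p=config.grade_probs)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 25, 95)

    corr = (config.ig_correlation if config.ig_correlation is not None
            else default_ig_correlation())
    eig = np.linalg.eigvalsh(corr.to_numpy())
    if eig.min() < -1e-8:
        raise ValueError("Ig correlation matrix is not positive semi-definite")
    cov = corr.to_numpy() * config.ig_sd**2
    ig = rng.multivariate_normal(
        np.full(len(corr), config.ig_mean), cov, size=n, method="cholesky")
    ig_df = pd.DataFrame(ig, columns=list(corr.columns))

    b = config.beta_clinical
    lp = (
        b["node_pos"] * node + b["size_gt20"] * size + b["er_pos"] * er_pos
        + b["her2_amp"] * her2 + b["grade3"] * (grade == 3)
        + b["age_per_year"] * (age - config.age_mean) + b["chemo"] * chemo
    )
    active = config.active_ig
    z_active = (ig_df[active] - config.ig_mean) / config.ig_sd  # per-SD effect
    lp = lp + config.beta_ig[active] * z_active

    lam = config.baseline_hazard * np.exp(lp)
    out = {"sample": [f"S{i:05d}" for i in range(n)]}
    for endpoint, frac in (("os", config.event_frac_os), ("rfs", config.event_frac_rfs)):
        t_event = rng.exponential(1.0 / lam)
        mu = _calibrate_censor_rate(lam, frac)
        t_cens = rng.exponential(1.0 / mu, size=n)
        out[f"{endpoint}_time"] = np.minimum(t_event, t_cens)
        out[f"{endpoint}_event"] = (t_event <= t_cens).astype(int)

    df = pd.DataFrame(out).set_index("sample")
    df["age"] = age
    df["node_status"] = np.where(node, "positive", "negative")
    df["tumor_size"] = np.where(size, ">20mm", "<=20mm")
    df["er_status"] = np.where(er_pos, "positive", "negative")
    df["pr_status"] = np.where(pr_pos, "positive", "negative")
    df["her2"] = np.where(her2, "amplified", "not")
    df["grade"] = grade
    df["pam50"] = pam50
    df["chemo"] = np.where(chemo, "yes", "no")
    df["endocrine"] = np.where(endo, "yes", "no")
    for cls in corr.columns:
        df[cls] = ig_df[cls].to_numpy()

    if config.missing_fraction > 0:
        clinical = ["node_status", "tumor_size", "er_status", "pr_status",
                    "her2", "grade", "pam50"]
        for col in clinical:
            mask = rng.random(n) < config.missing_fraction
            df.loc[mask, col] = np.nan

    true_betas = {active: config.beta_ig[active], **config.beta_clinical}
    return df, true_betas


# ---------------------------------------------------------------------------
# Expression-matrix simulation with a planted co-expressed gene set
# ---------------------------------------------------------------------------


def simulate_expression_matrix(
    n_samples: int = 200,
    n_genes: int = 500,
    planted_size: int = 20,
    noise_sd: float = 0.3,
    n_random_sets: int = 30,
    random_set_size: int = 25,
    target: str = "IGHG1",
    seed: int = 0,
) -> tuple[pd.DataFrame, GeneSetCollection, str]:
    """Samples × genes matrix with a gene set co-expressed with ``target``.

    The planted genes equal the target plus Gaussian noise of SD
    ``noise_sd`` (``0`` gives exact correlation 1); all other genes are
    independent standard normals.  The returned collection contains the
    planted set (named ``planted_set``) among random sets drawn from the
    background genes.
    """
    if planted_size >= n_genes:
        raise ValueError("planted set must be smaller than the gene universe")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    planted = [f"PL{i:03d}" for i in range(planted_size)]
    background = [f"G{i:04d}" for i in range(n_genes - planted_size - 1)]

    tvals = rng.standard_normal(n_samples)
    data = {target: tvals}
    for g in planted:
        data[g] = tvals + noise_sd * rng.standard_normal(n_samples)
    for g in background:
        data[g] = rng.standard_normal(n_samples)
    expr = pd.DataFrame(data, index=samples)

    sets = {"planted_set": list(planted)}
    for i in range(n_random_sets):
        sets[f"random_set_{i:02d}"] = list(
            rng.choice(background, size=min(random_set_size, len(background)),
                       replace=False)
        )
    collection = GeneSetCollection(sets=sets, universe=list(expr.columns))
    return expr, collection, "planted_set"
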