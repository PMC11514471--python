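"""Synthetic small-RNA-seq data with planted ground truth.

The generator emulates a skeletal-muscle microtranscriptome experiment:
hairpin precursors with annotated 5p/3p arms, genomic clusters of hairpins
co-located within a polycistron-scale window, negative-binomially distributed
per-sample counts carrying planted cluster-shared ("transcript-level") and
miRNA-private ("posttranscriptional") fold changes, isomiR end modifications
(trimming, templated 3' extension, non-templated A/U tails) with
group-dependent frequencies, and adapter-ligated FASTQ reads with the
4N-random-flank library chemistry.

Hairpin sequences are random: secondary structure plays no role downstream.
The four bases flanking each mature arm inside the hairpin are constrained to
G/C so that a non-templated U or A tail always mismatches the template — the
planted modification class is then unambiguous.  Read names encode the
ground-truth origin and modification (``mature|sample|serial|mod``), a
non-standard but FASTQ-legal convention used by the oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ConfigurationError, CountMatrix, HairpinRecord, Locus, MatureAnnotation, rng_for
from .io import write_fasta, write_fastq, write_gff3

_BASES = np.array(list("ACGT"))
# Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: How far a singleton hairpin must sit from anything else (polycistron scale).
CLUSTER_GAP_BP = 50_000


@dataclass(frozen=True)
class IsomirProfile:
    """Per-group probabilities of end modifications; the remainder is canonical.

    At most one modification event is planted per read.  Tail / trim lengths
    are geometric with success probability ``tail_geometric_p`` (support 1+).
    """

    p_trim3: float = 0.0
    p_trim5: float = 0.0
    p_nta_u: float = 0.0
    p_nta_a: float = 0.0
    p_templated_ext: float = 0.0
    tail_geometric_p: float = 0.6

    def validate(self) -> None:
        for name in ("p_trim3", "p_trim5", "p_nta_u", "p_nta_a", "p_templated_ext",
                     "tail_geometric_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"isomir_profile.{name} must be in [0, 1], got {v}")
        total = (self.p_trim3 + self.p_trim5 + self.p_nta_u + self.p_nta_a
                 + self.p_templated_ext)
        if total > 1.0 + 1e-12:
            raise ConfigurationError(
                f"isomir_profile probabilities sum to {total:.3f} > 1"
            )

    @property
    def event_probs(self) -> dict[str, float]:
        p = {
            "trim3": self.p_trim3,
            "trim5": self.p_trim5,
            "nta_u": self.p_nta_u,
            "nta_a": self.p_nta_a,
            "ext3": self.p_templated_ext,
        }
        p["canonical"] = max(0.0, 1.0 - sum(p.values()))
        return p


@dataclass(frozen=True)
class PlantedEffect:
    """A fold change planted on a whole cluster or a single mature miRNA.

    Cluster-scope effects apply identically to every mature arm of every
    hairpin in the cluster (the transcript-level mechanism); mirna-scope
    effects apply to exactly one mature id (posttranscriptional).
    """

    scope: str  # 'cluster' | 'mirna'
    target_id: str
    log2fc: float
    groups_affected: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.scope not in ("cluster", "mirna"):
            raise ConfigurationError(f"PlantedEffect.scope must be cluster|mirna, got {self.scope}")
        object.__setattr__(self, "groups_affected", tuple(self.groups_affected))


@dataclass
class SimulationConfig:
    seed: int = 0
    n_hairpins: int = 30
    n_clusters: int = 4
    cluster_size: int = 3
    cluster_span_bp: int = 40_000
    n_samples_per_group: int = 3
    groups: tuple[str, ...] = ("WT", "KO")
    baseline_mean_log_mu: float = 5.0
    baseline_mean_log_sigma: float = 1.2
    dispersion: float = 0.05
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    isomir_profile: IsomirProfile | dict[str, IsomirProfile] = field(
        default_factory=IsomirProfile
    )
    adapter: str = DEFAULT_ADAPTER
    random_flank_n: int = 4
    read_quality_q: int = 35
    noise_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        self.validate()

    def validate(self) -> None:
        if self.n_hairpins < 0 or self.n_clusters < 0:
            raise ConfigurationError("n_hairpins and n_clusters must be non-negative")
        if self.n_hairpins < self.n_clusters:
            raise ConfigurationError("n_hairpins must be >= n_clusters")
        if self.cluster_size < 1:
            raise ConfigurationError("cluster_size must be >= 1")
        if self.cluster_span_bp <= 0:
            raise ConfigurationError("cluster_span_bp must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.n_samples_per_group < 1:
            raise ConfigurationError("n_samples_per_group must be >= 1")
        if not self.groups:
            raise ConfigurationError("groups must be non-empty")
        if len(self.adapter) < 8:
            raise ConfigurationError("adapter must be at least 8 nt")
        if self.random_flank_n < 0:
            raise ConfigurationError("random_flank_n must be >= 0")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ConfigurationError("noise_fraction must be in [0, 1]")
        for prof in self._profiles().values():
            prof.validate()
        for eff in self.planted_effects:
            unknown = set(eff.groups_affected) - set(self.groups)
            if unknown:
                raise ConfigurationError(
                    f"planted_effects: unknown groups {sorted(unknown)} for {eff.target_id}"
                )

    def _profiles(self) -> dict[str, IsomirProfile]:
        if isinstance(self.isomir_profile, IsomirProfile):
            return {g: self.isomir_profile for g in self.groups}
        missing = set(self.groups) - set(self.isomir_profile)
        if missing:
            raise ConfigurationError(f"isomir_profile missing groups {sorted(missing)}")
        return dict(self.isomir_profile)

    def profile_for(self, group: str) -> IsomirProfile:
        return self._profiles()[group]


@dataclass
class GroundTruth:
    """Planted truth accompanying one simulated dataset.

    ``matures`` is indexed by mature id with columns hairpin_id, arm,
    cluster_id (empty string for singletons), baseline_mean, regulation_label
    and (time courses only) template.  ``log2fc`` holds the per-group total
    planted log2 offset relative to baseline; ``group_means`` the expected NB
    means; ``realized_means`` is filled in by ``simulate_counts``.
    ``mod_freqs`` maps group -> IsomirProfile.  ``hairpins`` carries the
    simulated records so read-level stages need no re-parsing.
    """

    matures: pd.DataFrame
    log2fc: pd.DataFrame
    group_means: pd.DataFrame
    mod_freqs: dict[str, IsomirProfile]
    hairpins: list[HairpinRecord]
    realized_means: pd.DataFrame | None = None

    def true_log2fc(self, group_a: str, group_b: str) -> pd.Series:
        """Planted log2 fold change of group_b relative to group_a."""
        return self.log2fc[group_b] - self.log2fc[group_a]

    def to_tsv(self) -> str:
        return self.matures.join(self.log2fc.add_prefix("log2fc_")).rename_axis(
            "mature_id"
        ).to_csv(sep="\t")


# ---------------------------------------------------------------------------
# annotation


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _make_hairpin(rng: np.random.Generator, hid: str, idx: int) -> HairpinRecord:
    """Random hairpin: lead | 5p arm | loop | 3p arm | tail, 60-110 nt.

    The 4 bases adjacent to each arm boundary (inside lead/loop/tail) are
    drawn from {G, C} so planted A/U tails always mismatch the template.
    """
    lead_n = int(rng.integers(5, 9))
    arm5_n = int(rng.integers(20, 24))
    loop_n = int(rng.integers(10, 18))
    arm3_n = int(rng.integers(20, 24))
    tail_n = int(rng.integers(5, 9))

    def guarded(n: int, guard_left: bool, guard_right: bool) -> str:
        s = list(_random_seq(rng, n))
        if guard_left:
            for i in range(min(4, n)):
                s[i] = _random_seq(rng, 1, "GC")
        if guard_right:
            for i in range(min(4, n)):
                s[-1 - i] = _random_seq(rng, 1, "GC")
        return "".join(s)

    lead = guarded(lead_n, guard_left=False, guard_right=True)
    arm5 = _random_seq(rng, arm5_n)
    loop = guarded(loop_n, guard_left=True, guard_right=True)
    arm3 = _random_seq(rng, arm3_n)
    tail = guarded(tail_n, guard_left=True, guard_right=False)
    seq = lead + arm5 + loop + arm3 + tail
    m5 = MatureAnnotation(f"{hid.replace('mir', 'miR')}-5p", "5p", lead_n, lead_n + arm5_n)
    s3 = lead_n + arm5_n + loop_n
    m3 = MatureAnnotation(f"{hid.replace('mir', 'miR')}-3p", "3p", s3, s3 + arm3_n)
    return HairpinRecord(hid, seq, matures=[m5, m3])


def generate_annotation(
    config: SimulationConfig,
) -> tuple[str, str, GroundTruth]:
    """Hairpin FASTA text, miRBase-dialect GFF3 text, and the planted truth.

    Clustered hairpins share a chromosome and strand with all pairwise
    distances below ``cluster_span_bp``; singletons are isolated by more than
    the polycistron window from anything else.
    """
    config.validate()
    rng = rng_for(config.seed, 1)
    hairpins: list[HairpinRecord] = []
    cluster_of: dict[str, str] = {}

    n_digits = max(3, len(str(config.n_hairpins)))
    ids = [f"sim-mir-{i + 1:0{n_digits}d}" for i in range(config.n_hairpins)]
    for i, hid in enumerate(ids):
        hairpins.append(_make_hairpin(rng, hid, i))

    # cluster membership: fill clusters greedily, remainder are singletons
    k = 0
    for c in range(config.n_clusters):
        members = ids[k : k + config.cluster_size]
        k += len(members)
        for hid in members:
            cluster_of[hid] = f"cluster_{c + 1}"

    # genomic placement: one chromosome per cluster; singletons widely spaced
    by_cluster: dict[str, list[HairpinRecord]] = {}
    for h in hairpins:
        by_cluster.setdefault(cluster_of.get(h.hairpin_id, ""), []).append(h)
    for ci, (cid, members) in enumerate(sorted(by_cluster.items())):
        if cid == "":
            continue
        chrom = f"chr{ci + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        base = int(rng.integers(1_000_000, 2_000_000))
        slots = np.arange(0, config.cluster_span_bp - 200, 500)
        offsets = np.sort(rng.choice(slots, size=len(members), replace=False))
        for h, off in zip(members, offsets):
            h.locus = Locus(chrom, strand, base + int(off))
    singles = by_cluster.get("", [])
    for si, h in enumerate(singles):
        h.locus = Locus("chrU", "+", 1_000_000 + si * (4 * CLUSTER_GAP_BP))

    # baselines, planted offsets and labels
    mature_rows = []
    for h in hairpins:
        for m in h.matures:
            mature_rows.append(
                {
                    "mature_id": m.mature_id,
                    "hairpin_id": h.hairpin_id,
                    "arm": m.arm,
                    "cluster_id": cluster_of.get(h.hairpin_id, ""),
                }
            )
    matures = pd.DataFrame(mature_rows).set_index("mature_id")
    matures["baseline_mean"] = np.exp(
        rng.normal(config.baseline_mean_log_mu, config.baseline_mean_log_sigma, len(matures))
    )

    log2fc = pd.DataFrame(0.0, index=matures.index, columns=list(config.groups))
    has_cluster_eff = pd.Series(False, index=matures.index)
    has_mirna_eff = pd.Series(False, index=matures.index)
    known_targets = set(matures.index) | set(cluster_of.values())
    for eff in config.planted_effects:
        if eff.target_id not in known_targets:
            raise ConfigurationError(f"planted_effects: unknown target {eff.target_id}")
        if eff.scope == "cluster":
            hit = matures["cluster_id"] == eff.target_id
            has_cluster_eff |= hit
        else:
            hit = matures.index == eff.target_id
            has_mirna_eff |= hit
        for g in eff.groups_affected:
            log2fc.loc[hit, g] += eff.log2fc

    label = pd.Series("null", index=matures.index)
    label[has_mirna_eff] = "posttranscriptional"
    label[has_cluster_eff] = "transcript_level"  # cluster effect dominates when both
    matures["regulation_label"] = label

    group_means = pd.DataFrame(
        matures["baseline_mean"].to_numpy()[:, None] * 2.0 ** log2fc.to_numpy(),
        index=matures.index,
        columns=log2fc.columns,
    )
    truth = GroundTruth(
        matures=matures,
        log2fc=log2fc,
        group_means=group_means,
        mod_freqs=config._profiles(),
        hairpins=hairpins,
    )
    return write_fasta((h.hairpin_id, h.sequence) for h in hairpins), write_gff3(hairpins), truth


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0.0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.negative_binomial(shape, shape / (shape + mean))


def sample_names(config: SimulationConfig) -> dict[str, list[str]]:
    return {
        g: [f"{g}_{r + 1}" for r in range(config.n_samples_per_group)]
        for g in config.groups
    }


def simulate_counts(config: SimulationConfig, truth: GroundTruth) -> CountMatrix:
    """Draw per-mature per-sample counts from the planted NB model.

    mean = baseline * 2^(sum of applicable planted log2fc); variance
    mean + dispersion * mean^2 (Poisson when dispersion is 0).
    """
    rng = rng_for(config.seed, 2)
    names = sample_names(config)
    cols: dict[str, np.ndarray] = {}
    for g in config.groups:
        mu = truth.group_means[g].to_numpy()
        for s in names[g]:
            cols[s] = _nb_draw(rng, mu, config.dispersion)
    counts = pd.DataFrame(cols, index=truth.group_means.index)
    samples = pd.DataFrame(
        {"condition": [g for g in config.groups for _ in names[g]]},
        index=[s for g in config.groups for s in names[g]],
    )
    realized = pd.DataFrame(index=counts.index, columns=list(config.groups), dtype=float)
    for g in config.groups:
        realized[g] = counts[names[g]].mean(axis=1)
    truth.realized_means = realized
    return CountMatrix(counts, samples)


# ---------------------------------------------------------------------------
# reads


def _geometric_len(rng: np.random.Generator, p: float) -> int:
    if p >= 1.0:
        return 1
    return int(rng.geometric(p))


def _modify_read(
    rng: np.random.Generator,
    hairpin: HairpinRecord,
    mature: MatureAnnotation,
    event: str,
    profile: IsomirProfile,
) -> tuple[str, str]:
    """Apply one planted modification; returns (sequence, mod tag)."""
    seq = hairpin.sequence
    s, e = mature.start, mature.end
    if event == "canonical":
        return seq[s:e], "canonical"
    if event == "trim3":
        k = min(_geometric_len(rng, profile.tail_geometric_p), 4, len(mature) - 15)
        return seq[s : e - k], f"trim3={k}"
    if event == "trim5":
        k = min(_geometric_len(rng, profile.tail_geometric_p), 4, len(mature) - 15)
        return seq[s + k : e], f"trim5={k}"
    if event == "ext3":
        k = min(_geometric_len(rng, profile.tail_geometric_p), len(seq) - e)
        if k == 0:
            return seq[s:e], "canonical"
        return seq[s : e + k], f"ext3={k}"
    if event in ("nta_u", "nta_a"):
        base = "T" if event == "nta_u" else "A"
        k = _geometric_len(rng, profile.tail_geometric_p)
        return seq[s:e] + base * k, f"nta3={base * k}"
    raise ValueError(event)


def simulate_reads(
    config: SimulationConfig, truth: GroundTruth, counts: CountMatrix
) -> dict[str, str]:
    """Per-sample FASTQ text realizing the count matrix read by read.

    Every count in ``counts`` becomes exactly one read:
    optional 5' random flank + modified mature + optional 3' random flank +
    adapter, at constant quality.  An optional uniform fraction of random
    noise reads is appended (named ``noise|...``) on top of the counted reads.
    """
    config.validate()
    rng = rng_for(config.seed, 3)
    hp = {h.hairpin_id: h for h in truth.hairpins}
    fastqs: dict[str, str] = {}
    for sample in counts.sample_ids:
        group = counts.condition(sample)
        profile = config.profile_for(group)
        probs = profile.event_probs
        events = list(probs)
        pvec = np.array([probs[ev] for ev in events])
        reads: list[tuple[str, str, int]] = []
        for mature_id, n in counts.counts[sample].items():
            h = hp[truth.matures.loc[mature_id, "hairpin_id"]]
            m = h.mature(mature_id)
            drawn = rng.choice(len(events), size=int(n), p=pvec)
            for i, ev_i in enumerate(drawn):
                seq, tag = _modify_read(rng, h, m, events[ev_i], profile)
                if config.random_flank_n:
                    seq = (
                        _random_seq(rng, config.random_flank_n)
                        + seq
                        + _random_seq(rng, config.random_flank_n)
                    )
                reads.append(
                    (f"{mature_id}|{sample}|{i}|{tag}", seq + config.adapter,
                     config.read_quality_q)
                )
        if config.noise_fraction > 0.0:
            n_noise = int(round(config.noise_fraction * len(reads)))
            for j in range(n_noise):
                seq = _random_seq(rng, int(rng.integers(18, 28)))
                if config.random_flank_n:
                    seq = (
                        _random_seq(rng, config.random_flank_n)
                        + seq
                        + _random_seq(rng, config.random_flank_n)
                    )
                reads.append((f"noise|{sample}|{j}|noise", seq + config.adapter,
                              config.read_quality_q))
        fastqs[sample] = write_fastq(reads)
    return fastqs


# ---------------------------------------------------------------------------
# time course


def _template_shapes(T: int) -> dict[str, np.ndarray]:
    """Named trajectory templates on a 0..1 scale over T time points."""
    x = np.linspace(0.0, 1.0, T)
    mid = np.sin(np.pi * x)
    step_last = (np.arange(T) == T - 1).astype(float)
    step_first = (np.arange(T) == 0).astype(float)
    shapes = {
        "flat": np.zeros(T),
        "monotone_up": x,
        "monotone_down": 1.0 - x,
        "transient_up": mid / mid.max(),
        "transient_down": 1.0 - mid / mid.max(),
        "late_up": step_last,
        "early_down": step_first,
    }
    return shapes


TEMPLATE_NAMES = tuple(_template_shapes(4).keys())


def simulate_timecourse(
    config: SimulationConfig,
    patterns: Sequence[str],
    amplitude: float = 3.0,
) -> tuple[CountMatrix, GroundTruth]:
    """Counts over the time points in ``config.groups`` following planted templates.

    Each mature follows one template (assigned round-robin) whose dynamic
    range is ``amplitude`` log2 units; the truth records template membership
    in ``matures['template']``.
    """
    if len(config.groups) < 2:
        raise ConfigurationError("groups: a time course needs >= 2 time points")
    if config.n_samples_per_group < 2:
        raise ConfigurationError("n_samples_per_group: need >= 2 replicates per time point")
    if not patterns:
        raise ConfigurationError("patterns: need at least one trajectory template")
    shapes = _template_shapes(len(config.groups))
    unknown = set(patterns) - set(shapes)
    if unknown:
        raise ConfigurationError(f"patterns: unknown templates {sorted(unknown)}")

    _, _, truth = generate_annotation(replace(config, planted_effects=[]))
    templates = [patterns[i % len(patterns)] for i in range(len(truth.matures))]
    truth.matures["template"] = templates
    truth.matures.loc[truth.matures["template"] == "flat", "regulation_label"] = "null"
    offsets = np.stack([amplitude * shapes[t] for t in templates])
    truth.log2fc = pd.DataFrame(offsets, index=truth.matures.index, columns=list(config.groups))
    truth.group_means = pd.DataFrame(
        truth.matures["baseline_mean"].to_numpy()[:, None] * 2.0**offsets,
        index=truth.matures.index,
        columns=list(config.groups),
    )
    cm = simulate_counts(config, truth)
    cm.samples["timepoint"] = cm.samples["condition"]
    return cm, truth
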