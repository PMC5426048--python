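"""Synthetic pooled-competition experiments with known ground truth.

The generative model: strain ``i`` with relative fitness ``gamma_i`` grows as
``2**(gamma_i * G)`` where ``G`` counts *pool generations* (doublings of total
pool biomass).  Back-dilutions rescale cell counts but not proportions, so the
expected proportion of strain ``i`` at generation ``G`` is

    p_i(G) = p0_i * 2**(gamma_i * G) / sum_j p0_j * 2**(gamma_j * G).

Sequencing of a sample draws ``depth`` reads per barcode position from a
multinomial over those proportions (optionally Dirichlet-perturbed to model
PCR/sequencing overdispersion).  Optionally the pool passes through a finite
bottleneck of cells at each sampling/back-dilution point, and optionally an
ethanol-style "takeover" regime slows the majority of strains after a given
generation while a minority keeps growing.

Ground truth (per-strain gamma and initial proportions) is recorded so every
downstream stage of the analysis has a parameter-recovery test surface.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimConfig

NUCLEOTIDES = np.array(list("ACGT"))

# Flanking common-primer segments for the two barcode positions (sequences from
# the screen's amplification primers; the 3' flank is the reverse complement of
# the reverse primer's annealing region).  Read layout per position:
#   5-nt sample tag + primer5 + 20-nt strain barcode + primer3
PRIMERS: dict[str, tuple[str, str]] = {
    "B1": ("GATGTCCACGAGGTCTCT", "CGTACGCTGCAGGTCGAC"),
    "B2": ("CGAGCTCGAATTCATCGAT", "CTACGAGACCGACACCG"),
}

BARCODE_POSITIONS = ("B1", "B2")

# stage offsets used to derive independent, reproducible streams from one seed
_STAGE = {"reference": 0, "truth": 1, "propagate": 2, "sample": 3, "fastq": 4, "tags": 5}


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STAGE[stage]]))


def _bio_rep_labels(n: int) -> list[str]:
    if n <= 26:
        return list(string.ascii_uppercase[:n])
    return [f"R{i + 1}" for i in range(n)]


def strain_ids(n: int) -> list[str]:
    return [f"strain_{i:05d}" for i in range(n)]


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    Attributes
    ----------
    gamma : per-strain relative fitness (doublings per pool generation).
    p0 : initial proportions, one column per biological replicate; each
        column sums to 1.
    survivor : boolean flags for the takeover-resistant minority (all False
        when no takeover regime is configured).
    """

    gamma: pd.Series
    p0: pd.DataFrame
    survivor: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"strain_id": self.gamma.index, "gamma": self.gamma.values})
        for rep in self.p0.columns:
            out[f"p0_{rep}"] = self.p0[rep].values
        out["survivor"] = self.survivor.values.astype(int)
        return out

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SimTruth":
        df = pd.read_csv(path, sep="\t", dtype={"strain_id": str}).set_index("strain_id")
        p0_cols = [c for c in df.columns if c.startswith("p0_")]
        p0 = df[p0_cols].rename(columns={c: c[3:] for c in p0_cols})
        return cls(
            gamma=df["gamma"],
            p0=p0,
            survivor=df["survivor"].astype(bool),
        )


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw per-strain fitness and initial proportions for one experiment.

    Deterministic given ``config.seed``.  Fitness deficits are assigned by
    independent Bernoulli draws (so the realized affected fraction fluctuates
    binomially around ``fitness_spec.fraction_affected``); initial proportions
    are drawn independently for each biological replicate, emulating the two
    independently pooled libraries.
    """
    config.validate()
    rng = _rng(config, "truth")
    strains = strain_ids(config.n_strains)
    n = config.n_strains

    fs = config.fitness_spec
    gamma = np.ones(n)
    if fs.fraction_affected > 0:
        affected = rng.random(n) < fs.fraction_affected
        gamma[affected] = rng.uniform(fs.effect_low, fs.effect_high, affected.sum())
    gamma_s = pd.Series(gamma, index=strains, name="gamma")
    if config.gamma_overrides:
        for sid, g in config.gamma_overrides.items():
            if sid not in gamma_s.index:
                raise ConfigurationError(f"gamma override for unknown strain {sid!r}")
            if g <= 0:
                raise ConfigurationError(f"gamma must be > 0, got {g} for {sid!r}")
            gamma_s[sid] = g

    reps = _bio_rep_labels(config.n_bio_reps)
    p0 = {}
    for rep in reps:
        if config.init_spec.kind == "uniform":
            w = np.ones(n)
        else:
            w = np.exp(rng.normal(0.0, config.init_spec.sigma, n))
        p0[rep] = w / w.sum()
    p0_df = pd.DataFrame(p0, index=strains)

    survivor = np.zeros(n, dtype=bool)
    if config.takeover is not None:
        n_surv = max(1, round(config.takeover.survivor_fraction * n))
        survivor[rng.choice(n, size=n_surv, replace=False)] = True

    return SimTruth(gamma=gamma_s, p0=p0_df, survivor=pd.Series(survivor, index=strains))


def _growth_exponent(truth: SimTruth, config: SimConfig, g: float) -> np.ndarray:
    """log2 fold-expansion of each strain at pool generation ``g``."""
    gamma = truth.gamma.values
    if config.takeover is None or g <= config.takeover.g_star:
        return gamma * g
    tk = config.takeover
    expo = gamma * tk.g_star + gamma * tk.slowdown * (g - tk.g_star)
    return np.where(truth.survivor.values, gamma * g, expo)


def propagate_pool(truth: SimTruth, config: SimConfig) -> dict[str, pd.DataFrame]:
    """Strain proportions at each scheduled generation, per biological replicate.

    Returns a mapping bio_rep -> DataFrame (strains x timepoints) of
    proportions summing to 1 in every column.  Without a bottleneck the
    propagation is deterministic (expected proportions); with a bottleneck,
    the pool is resampled multinomially down to ``config.bottleneck`` cells at
    each scheduled point, approximating hypergeometric subsampling of a large
    culture at back-dilution.
    """
    config.validate()
    sched = np.asarray(config.schedule, dtype=float)
    rng = _rng(config, "propagate")
    out: dict[str, pd.DataFrame] = {}
    for rep in truth.p0.columns:
        p0 = truth.p0[rep].values
        cols = {}
        if config.bottleneck is None:
            for t, g in enumerate(sched):
                w = p0 * np.exp2(_growth_exponent(truth, config, g))
                cols[t] = w / w.sum()
        else:
            p_prev = p0
            e_prev = np.zeros(config.n_strains)
            for t, g in enumerate(sched):
                e_now = _growth_exponent(truth, config, g)
                w = p_prev * np.exp2(e_now - e_prev)
                p = w / w.sum()
                counts = rng.multinomial(config.bottleneck, p)
                p = counts / counts.sum()
                cols[t] = p
                p_prev, e_prev = p, e_now
        out[rep] = pd.DataFrame(cols, index=truth.p0.index)
    return out


COUNT_COLUMNS = [
    "strain_id",
    "barcode_position",
    "pool",
    "background",
    "condition",
    "bio_rep",
    "tech_rep",
    "timepoint_index",
    "generations",
    "count",
]


def sample_reads(
    proportions: dict[str, pd.DataFrame],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw sequencing counts for every sample of the experiment.

    One multinomial of total ``config.depth`` per (bio_rep, timepoint,
    barcode_position, tech_rep); B1 and B2 and the technical replicates are
    independent draws from the same time-point proportions.  With finite
    ``overdispersion`` the proportions of each draw are first perturbed by a
    Dirichlet sample with concentration ``overdispersion * p``.

    Returns a long-format CountTable (columns ``COUNT_COLUMNS``).
    """
    config.validate()
    if rng is None:
        rng = _rng(config, "sample")
    sched = list(config.schedule)
    frames = []
    for rep, props in proportions.items():
        strains = props.index.to_numpy()
        for t in props.columns:
            p = props[t].to_numpy()
            for pos in BARCODE_POSITIONS:
                for tech in range(1, config.n_tech_reps + 1):
                    if config.overdispersion is not None:
                        alpha = config.overdispersion * p
                        # Dirichlet with any zero concentration is degenerate;
                        # clip to a tiny floor so extinct strains stay at ~0
                        q = rng.dirichlet(np.clip(alpha, 1e-12, None))
                    else:
                        q = p
                    counts = rng.multinomial(config.depth, q)
                    frames.append(
                        pd.DataFrame(
                            {
                                "strain_id": strains,
                                "barcode_position": pos,
                                "pool": config.pool,
                                "background": config.pool,
                                "condition": config.condition,
                                "bio_rep": rep,
                                "tech_rep": tech,
                                "timepoint_index": t,
                                "generations": sched[t],
                                "count": counts,
                            }
                        )
                    )
    table = pd.concat(frames, ignore_index=True)
    return table[COUNT_COLUMNS]


def simulate_counts(config: SimConfig) -> tuple[SimTruth, pd.DataFrame]:
    """Convenience wrapper: truth -> propagation -> counts in one call."""
    truth = simulate_truth(config)
    props = propagate_pool(truth, config)
    counts = sample_reads(props, config)
    return truth, counts


# ---------------------------------------------------------------------------
# Barcode reference and FASTQ emission
# ---------------------------------------------------------------------------


def _random_tags(rng: np.random.Generator, n: int, length: int, min_dist: int) -> np.ndarray:
    """Random DNA tags with pairwise Hamming distance >= min_dist.

    Works on a (n, length) uint8 matrix; offending rows are redrawn until the
    distance constraint holds (collisions are vanishingly rare for 20-mers).
    """
    codes = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    while True:
        bad = set()
        # chunked all-pairs Hamming scan
        for i0 in range(0, n, 256):
            block = codes[i0 : i0 + 256]
            d = (block[:, None, :] != codes[None, :, :]).sum(axis=2)
            ii, jj = np.nonzero(d < min_dist)
            for bi, j in zip(ii, jj):
                i = i0 + bi
                if i < j:
                    bad.add(j)
        if not bad:
            break
        idx = sorted(bad)
        codes[idx] = rng.integers(0, 4, size=(len(idx), length), dtype=np.uint8)
    return codes


def _codes_to_seqs(codes: np.ndarray) -> list[str]:
    return ["".join(row) for row in NUCLEOTIDES[codes]]


def make_reference(config: SimConfig) -> pd.DataFrame:
    """Synthetic strain/barcode reference table.

    Up-tags (B1) and down-tags (B2) are generated with pairwise Hamming
    distance >= 3 within each tag class, so that one-mismatch matching is
    collision-free by construction.
    """
    config.validate()
    rng = _rng(config, "reference")
    strains = strain_ids(config.n_strains)
    up = _codes_to_seqs(_random_tags(rng, config.n_strains, config.barcode_len, 3))
    down = _codes_to_seqs(_random_tags(rng, config.n_strains, config.barcode_len, 3))
    return pd.DataFrame(
        {
            "strain_id": strains,
            "gene_name": [f"GENE{i:05d}" for i in range(config.n_strains)],
            "up_tag": up,
            "down_tag": down,
            "pool": config.pool,
        }
    )


MANIFEST_COLUMNS = [
    "multiplex_tag",
    "pool",
    "background",
    "condition",
    "bio_rep",
    "tech_rep",
    "timepoint_index",
    "generations",
]


def make_tag_manifest(counts: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Assign a unique 5-nt multiplex tag to every sample in a CountTable."""
    samples = (
        counts[["pool", "background", "condition", "bio_rep", "tech_rep", "timepoint_index", "generations"]]
        .drop_duplicates()
        .sort_values(["pool", "condition", "bio_rep", "tech_rep", "timepoint_index"])
        .reset_index(drop=True)
    )
    n = len(samples)
    if n > 4**config.tag_len:
        raise ConfigurationError(f"{n} samples exceed the {config.tag_len}-nt tag space")
    rng = _rng(config, "tags")
    # distance >= 2 guarantees uniqueness for exact-match demultiplexing
    tags = _codes_to_seqs(_random_tags(rng, n, config.tag_len, 2))
    samples.insert(0, "multiplex_tag", tags)
    return samples[MANIFEST_COLUMNS]


def _inject_errors(reads: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-base substitution errors on a (n_reads, read_len) uint8 code matrix."""
    if rate <= 0:
        return reads
    mask = rng.random(reads.shape) < rate
    n_err = int(mask.sum())
    if n_err:
        # substitute with one of the three *other* bases
        shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
        reads = reads.copy()
        reads[mask] = (reads[mask] + shift) % 4
    return reads


_CODE = {c: i for i, c in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.uint8)


def emit_fastq(
    counts: pd.DataFrame,
    reference: pd.DataFrame,
    config: SimConfig,
    out_dir: str | Path,
    manifest: pd.DataFrame | None = None,
) -> tuple[Path, Path]:
    """Write one FASTQ read per count, plus the sample-tag manifest.

    Reads are laid out ``tag + primer5 + strain_barcode + primer3`` with
    substitution errors applied at ``config.seq_error_rate`` uniformly over
    all positions.  Base qualities are constant ('I'); the counting pipeline
    never uses them.  Returns (fastq_path, manifest_path).
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        manifest = make_tag_manifest(counts, config)
    rng = _rng(config, "fastq")

    missing = set(counts["strain_id"]) - set(reference["strain_id"])
    if missing:
        raise KeyError(f"strains in counts missing from reference: {sorted(missing)[:5]}")

    tag_of = manifest.set_index(
        ["pool", "condition", "bio_rep", "tech_rep", "timepoint_index"]
    )["multiplex_tag"]
    barcode = {
        "B1": reference.set_index("strain_id")["up_tag"],
        "B2": reference.set_index("strain_id")["down_tag"],
    }

    fastq_path = out_dir / "reads.fastq"
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)

    read_no = 0
    with open(fastq_path, "w") as fh:
        for key, grp in counts.groupby(
            ["pool", "condition", "bio_rep", "tech_rep", "timepoint_index", "barcode_position"],
            sort=True,
        ):
            pos = key[-1]
            tag = tag_of[key[:-1]]
            p5, p3 = PRIMERS[pos]
            for sid, c in zip(grp["strain_id"], grp["count"]):
                if c <= 0:
                    continue
                template = _encode(tag + p5 + barcode[pos][sid] + p3)
                block = np.broadcast_to(template, (int(c), template.size))
                block = _inject_errors(np.ascontiguousarray(block), config.seq_error_rate, rng)
                qual = "I" * template.size
                for row in NUCLEOTIDES[block]:
                    read_no += 1
                    fh.write(f"@read_{read_no}\n{''.join(row)}\n+\n{qual}\n")
    return fastq_path, manifest_path
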