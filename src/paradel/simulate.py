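"""Synthetic tumor-cohort generator under a clonal-selection model.

The generative model: each tumor acquires a Poisson number of candidate HD
events; event start positions are drawn with weights elevated near TSGs,
fragile sites, telomeres and centromeres; event lengths are exponential with
a shorter mean inside fragile sites. A candidate event survives clonal
selection with probability ``min(1, tau^{#TSGs deleted} * prod_g s(g))`` over
the non-driver genes it fully deletes, where the survival multiplier ``s``
depends on the gene's dispensability class: essential genes are rarely
tolerated, singleton loss is tolerated less often than paralog loss, and
paralog survival is modulated by family size, closest-paralog sequence
identity and WGD origin. Hemizygous (LOH) events are selection-neutral.
Accepted events are emitted as ASCAT-style allele-specific segment tables
tiling each chromosome arm, directly consumable by :mod:`paradel.calling`.

A Monte-Carlo / grid oracle computes the expected paralog-vs-singleton odds
ratio implied by a configuration, independent of any one simulated cohort.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import annotation as anno
from .annotation import GenomeLayout
from .calling import map_genes_to_segments
from .features import MB, inverted_distance

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for annotation, events and clonal selection.

    Distances/lengths are bp unless suffixed ``_mb``. The default scale is a
    2,000-tumor cohort on a 22-chromosome, 20,000-gene genome; the HD event
    rate is compressed relative to a >10,000-sample patient cohort so that
    per-gene deletion frequencies at 2,000 samples are comparable.
    """

    # genome
    n_chromosomes: int = 22
    chrom_length: int = 120_000_000
    centromere_half_width: int = 1_000_000
    n_genes: int = 20_000
    gene_length_median: float = 25_000.0
    gene_length_log_sd: float = 1.0
    gene_length_min: int = 1_000
    gene_length_max: int = 2_000_000
    gene_overlap_fraction: float = 0.0
    # annotation
    paralog_fraction: float = 0.62
    family_size_geom_p: float = 0.29     # geometric family size, median 3
    identity_beta_a: float = 1.5         # closest-paralog identity ~ 0.2 + 0.8*Beta(a, b)
    identity_beta_b: float = 2.2
    wgd_fraction: float = 0.5
    n_tsgs: int = 90
    n_other_drivers: int = 150
    n_fragile_sites: int = 15
    fragile_width: int = 1_500_000
    essential_fraction_singleton: float = 0.15
    essential_fraction_paralog: float = 0.05
    # event model
    hd_events_per_tumor: float = 10.0
    alpha_tsg: float = 5.0
    beta_fragile: float = 5.0
    gamma_telcent: float = 2.0
    prox_cap_mb: float = 10.0
    hd_mean_length_fragile_mb: float = 0.34
    hd_mean_length_other_mb: float = 0.83
    loh_events_per_tumor: float = 20.0
    loh_mean_length_mb: float = 10.0
    loh_copy_neutral_fraction: float = 0.4
    loh_whole_arm_fraction: float = 0.3
    # selection
    s_essential: float = 0.1
    s_singleton: float = 0.5
    s_paralog: float = 1.0
    tau_tsg: float = 20.0
    wgd_penalty: float = 0.1
    small_family_penalty: float = 0.1
    low_identity_penalty: float = 0.2
    big_family_min: int = 4
    # cohort
    n_samples: int = 2_000

    def __post_init__(self):
        for name in ("s_essential", "s_singleton", "s_paralog", "tau_tsg",
                     "hd_events_per_tumor", "loh_events_per_tumor"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        for name in ("paralog_fraction", "wgd_fraction", "gene_overlap_fraction",
                     "essential_fraction_singleton", "essential_fraction_paralog",
                     "loh_copy_neutral_fraction", "loh_whole_arm_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise SimulationError(f"{name} must be in [0, 1]")

    def null(self) -> "SimulationConfig":
        """No dispensability differential, no context effects: every candidate
        event survives, placement is uniform and fragile sites neither attract
        events nor shorten them."""
        return replace(self, s_essential=1.0, s_singleton=1.0, s_paralog=1.0,
                       tau_tsg=1.0, alpha_tsg=0.0, beta_fragile=0.0,
                       gamma_telcent=0.0, wgd_penalty=0.0,
                       small_family_penalty=0.0, low_identity_penalty=0.0,
                       hd_mean_length_fragile_mb=self.hd_mean_length_other_mb)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class SimulatedAnnotation:
    """Annotated synthetic genome: gene models, attributes, regions, truth."""

    genes: pd.DataFrame            # canonical gene-model frame
    annotations: pd.DataFrame      # paralogy/driver/essentiality flags
    layout: GenomeLayout
    tsg_spans: pd.DataFrame        # chrom/start/end of TSG coding spans
    fragile_sites: pd.DataFrame
    survival: pd.Series            # per-gene survival multiplier s(g), index gene_id
    config: SimulationConfig


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated cohort: all candidate events with their
    acceptance probability and fate, plus per-gene survival multipliers."""

    events: pd.DataFrame           # sample, chrom, start, end, accept_p, accepted, fragile_ctx
    per_gene: pd.DataFrame         # gene_id, dispensability class, survival
    seed: int
    config_digest: str


def _gene_class(is_driver, is_tsg, essential, is_paralog) -> np.ndarray:
    cls = np.where(is_tsg, "tsg",
                   np.where(is_driver, "driver",
                            np.where(essential, "essential",
                                     np.where(is_paralog, "paralog", "singleton"))))
    return cls.astype(object)


def simulate_annotation(config: SimulationConfig, seed: int) -> SimulatedAnnotation:
    """Generate the annotated genome: deterministic given (config, seed).

    Genes are packed per chromosome arm with Dirichlet-distributed gaps and
    never cross the centromere gap; an ``gene_overlap_fraction`` of genes is
    placed overlapping its predecessor to exercise driver-overlap exclusion.
    Raises when the requested genes cannot fit on the genome.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA110]))
    C = config.n_chromosomes
    chroms = [str(i + 1) for i in range(C)]
    mid = config.chrom_length // 2
    cen = (mid - config.centromere_half_width, mid + config.centromere_half_width)
    layout = GenomeLayout(chrom_lengths={c: config.chrom_length for c in chroms},
                          centromeres={c: cen for c in chroms})

    # distribute genes over arms proportional to arm length
    arms = []
    for c in chroms:
        arms.append((c, 1, cen[0] - 1))
        arms.append((c, cen[1] + 1, config.chrom_length))
    arm_len = np.array([a2 - a1 + 1 for _, a1, a2 in arms], dtype=float)
    n_per_arm = rng.multinomial(config.n_genes, arm_len / arm_len.sum())

    mu = np.log(config.gene_length_median)
    rows = []
    gid = 0
    for (c, a1, a2), n in zip(arms, n_per_arm):
        if n == 0:
            continue
        lengths = np.clip(np.exp(rng.normal(mu, config.gene_length_log_sd, n)),
                          config.gene_length_min, config.gene_length_max).astype(np.int64)
        free = (a2 - a1 + 1) - int(lengths.sum())
        if free < 0:
            raise SimulationError(
                f"cannot pack {n} genes (total {lengths.sum()} bp) into arm of "
                f"{a2 - a1 + 1} bp on chromosome {c}")
        gaps = rng.dirichlet(np.ones(n + 1)) * free
        starts = (a1 + np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])])
                  ).astype(np.int64)
        if config.gene_overlap_fraction > 0 and n > 1:
            overlap = rng.random(n) < config.gene_overlap_fraction
            overlap[0] = False
            for i in np.flatnonzero(overlap):
                prev_end = starts[i - 1] + lengths[i - 1] - 1
                starts[i] = max(a1, prev_end - lengths[i] // 2)
        ends = starts + lengths - 1
        for s, e in zip(starts, ends):
            rows.append((f"G{gid:05d}", c, int(s), int(min(e, a2))))
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    genes["symbol"] = genes["gene_id"]
    genes = anno.read_gene_models(genes)

    n = len(genes)
    is_paralog = rng.random(n) < config.paralog_fraction
    family = np.where(is_paralog, rng.geometric(config.family_size_geom_p, n), 0)
    identity = np.where(
        is_paralog,
        0.2 + 0.8 * rng.beta(config.identity_beta_a, config.identity_beta_b, n),
        np.nan)
    wgd = is_paralog & (rng.random(n) < config.wgd_fraction)
    essential_p = np.where(is_paralog, config.essential_fraction_paralog,
                           config.essential_fraction_singleton)
    essential = rng.random(n) < essential_p

    n_drivers = config.n_tsgs + config.n_other_drivers
    if n_drivers > n:
        raise SimulationError("more drivers requested than genes")
    driver_idx = rng.choice(n, size=n_drivers, replace=False)
    is_tsg = np.zeros(n, dtype=bool)
    is_tsg[driver_idx[:config.n_tsgs]] = True
    is_driver = np.zeros(n, dtype=bool)
    is_driver[driver_idx] = True

    annotations = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "is_paralog": is_paralog,
        "family_size": family.astype(np.int64),
        "max_seq_identity": identity,
        "is_wgd": wgd,
        "is_driver": is_driver,
        "is_tsg": is_tsg,
        "essential_truth": essential,
    })

    # survival multipliers: drivers neutral (TSG effect enters through tau)
    s = np.full(n, config.s_singleton)
    s[is_paralog] = (config.s_paralog
                     * (1 - config.wgd_penalty * wgd[is_paralog])
                     * (1 - config.small_family_penalty
                        * (family[is_paralog] < config.big_family_min))
                     * (1 - config.low_identity_penalty * (1 - identity[is_paralog])))
    s[essential] = config.s_essential
    s[is_driver] = 1.0
    survival = pd.Series(np.clip(s, 0.0, 1.0), index=genes["gene_id"], name="survival")

    tsg_spans = genes.loc[is_tsg, ["chrom", "start", "end"]].reset_index(drop=True)

    frag_rows = []
    arm_p = arm_len / arm_len.sum()
    picks = rng.choice(len(arms), size=config.n_fragile_sites, p=arm_p, replace=True)
    for k in picks:
        c, a1, a2 = arms[k]
        w = min(config.fragile_width, a2 - a1)
        s0 = int(rng.integers(a1, a2 - w + 1))
        frag_rows.append((c, s0, s0 + w - 1))
    fragile = pd.DataFrame(frag_rows, columns=["chrom", "start", "end"])

    return SimulatedAnnotation(genes=genes, annotations=annotations, layout=layout,
                               tsg_spans=tsg_spans, fragile_sites=fragile,
                               survival=survival, config=config)


class _EventSampler:
    """Shared machinery for drawing candidate HD events and computing their
    clonal-survival probability; used by both the cohort generator and the
    expectation oracle so the two agree by construction of the event law
    (the oracle stays independent of selection bookkeeping downstream).

    Event origins may fall in a margin upstream of each arm; the surviving
    part of such an event is clipped to the arm. This makes the breakage
    process stationary across the arm (no artificial rate dip at arm starts)
    and produces telomere- and centromere-bound segments the way real ones
    arise: from breakpoints beyond the assayed boundary.
    """

    BIN = 200_000
    MARGIN = 5_000_000  # upstream start margin per arm, >> mean event length

    def __init__(self, ann: SimulatedAnnotation):
        self.ann = ann
        cfg = ann.config
        layout = ann.layout
        chroms = layout.chromosomes
        bins = []
        for ci, c in enumerate(chroms):
            L = layout.chrom_lengths[c]
            cs, ce = layout.centromeres[c]
            starts = np.arange(1, L + 1, self.BIN, dtype=np.int64)
            ends = np.minimum(starts + self.BIN - 1, L)
            bins.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends,
                                      "ci": ci, "margin_of": ""}))
            for arm, a0 in (("p", 1), ("q", ce + 1)):
                ms = np.arange(a0 - self.MARGIN, a0, self.BIN, dtype=np.int64)
                bins.append(pd.DataFrame({
                    "chrom": c, "start": ms,
                    "end": np.minimum(ms + self.BIN - 1, a0 - 1),
                    "ci": ci, "margin_of": arm}))
        grid = pd.concat(bins, ignore_index=True)
        mids = ((grid["start"] + grid["end"]) // 2)
        pts = grid.assign(start=mids.clip(lower=1), end=mids.clip(lower=1))
        cap = cfg.prox_cap_mb
        w = np.ones(len(grid))
        if cfg.alpha_tsg:
            w += cfg.alpha_tsg * inverted_distance(pts, ann.tsg_spans, cap).to_numpy() / cap
        if cfg.beta_fragile:
            w += cfg.beta_fragile * inverted_distance(pts, ann.fragile_sites, cap).to_numpy() / cap
        if cfg.gamma_telcent:
            tel = pd.concat([
                pd.DataFrame([(c, 1, 1) for c in chroms], columns=["chrom", "start", "end"]),
                pd.DataFrame([(c, layout.chrom_lengths[c], layout.chrom_lengths[c])
                              for c in chroms], columns=["chrom", "start", "end"]),
                pd.DataFrame([(c, *layout.centromeres[c]) for c in chroms],
                             columns=["chrom", "start", "end"]),
            ], ignore_index=True)
            w += cfg.gamma_telcent * inverted_distance(pts, tel, cap).to_numpy() / cap
        # no events originate inside the centromere assembly gap; margin bins
        # inherit the weight of the first bin of their arm and clip to it
        clip_lo = np.ones(len(grid), dtype=np.int64)
        is_margin = (grid["margin_of"] != "").to_numpy()
        ci_arr = grid["ci"].to_numpy()
        starts_arr = grid["start"].to_numpy()
        mids_arr = mids.to_numpy()
        for ci, c in enumerate(chroms):
            cs, ce = layout.centromeres[c]
            on_c = ci_arr == ci
            real = on_c & ~is_margin
            w[real & (mids_arr >= cs) & (mids_arr <= ce)] = 0.0
            q_first = starts_arr[real & (starts_arr > ce)].min()
            for arm, a0, first_start in (("p", 1, 1), ("q", ce + 1, q_first)):
                marg = on_c & (grid["margin_of"] == arm).to_numpy()
                first = real & (starts_arr == first_start)
                w[marg] = w[first][0]
                clip_lo[marg] = a0
        self.grid = grid
        self.clip_lo = clip_lo
        self.cum_w = np.cumsum(w)
        self.chrom_names = np.asarray(chroms, dtype=object)
        self.cen = np.array([layout.centromeres[c] for c in chroms])
        self.chrom_len = np.array([layout.chrom_lengths[c] for c in chroms])
        self.fragile_by_chrom = {
            c: g.sort_values("start")[["start", "end"]].to_numpy()
            for c, g in ann.fragile_sites.groupby("chrom")}
        surv = ann.survival.to_numpy()
        with np.errstate(divide="ignore"):
            self.log_s = np.log(surv)
        self.is_tsg = ann.annotations["is_tsg"].to_numpy()
        self.is_driver = ann.annotations["is_driver"].to_numpy()

    def draw_events(self, rng: np.random.Generator, m: int) -> pd.DataFrame:
        """Draw m candidate HD events (chrom index, start, end, fragile ctx).

        Events whose surviving extent is empty (origin too deep in a margin)
        come back with end < start and delete nothing.
        """
        total = self.cum_w[-1]
        k = np.searchsorted(self.cum_w, rng.random(m) * total, side="right")
        bstart = self.grid["start"].to_numpy()[k]
        bend = self.grid["end"].to_numpy()[k]
        ci = self.grid["ci"].to_numpy()[k]
        start = bstart + np.floor(rng.random(m) * (bend - bstart + 1)).astype(np.int64)
        frag = np.zeros(m, dtype=bool)
        chrom = self.chrom_names[ci]
        for c, arr in self.fragile_by_chrom.items():
            mask = chrom == c
            if not mask.any():
                continue
            idx = np.searchsorted(arr[:, 0], start[mask], side="right") - 1
            ok = (idx >= 0)
            hit = np.zeros(mask.sum(), dtype=bool)
            hit[ok] = start[mask][ok] <= arr[np.clip(idx[ok], 0, None), 1]
            frag[np.flatnonzero(mask)] = hit
        cfg = self.ann.config
        mean_len = np.where(frag, cfg.hd_mean_length_fragile_mb, cfg.hd_mean_length_other_mb) * MB
        length = np.maximum(1, rng.exponential(mean_len)).astype(np.int64)
        end = start + length - 1
        # events never cross the centromere gap or the chromosome end
        cs = self.cen[ci, 0]
        arm_end = np.where(start < cs, cs - 1, self.chrom_len[ci])
        # q-arm margin events originate in the gap but belong to the q arm
        arm_end = np.where(self.clip_lo[k] > cs, self.chrom_len[ci], arm_end)
        end = np.minimum(end, arm_end)
        start = np.maximum(start, self.clip_lo[k])
        return pd.DataFrame({"chrom": chrom, "start": start, "end": end,
                             "fragile_ctx": frag, "ci": ci})

    def accept_prob(self, events: pd.DataFrame) -> np.ndarray:
        """Clonal-survival probability per candidate event:
        min(1, tau^{#TSG fully deleted} * prod s(g) over non-driver genes)."""
        cfg = self.ann.config
        pairs = map_genes_to_segments(self.ann.genes, events, mode="full")
        log_p = np.zeros(len(events))
        n_tsg = np.zeros(len(events))
        if not pairs.empty:
            gi = pairs["gene_idx"].to_numpy()
            si = pairs["seg_idx"].to_numpy()
            contrib = np.where(self.is_driver[gi], 0.0, self.log_s[gi])
            with np.errstate(invalid="ignore"):
                np.add.at(log_p, si, contrib)
            np.add.at(n_tsg, si, self.is_tsg[gi].astype(float))
        with np.errstate(over="ignore"):
            p = np.exp(log_p + n_tsg * np.log(cfg.tau_tsg if cfg.tau_tsg > 0 else 1e-300))
        return np.minimum(1.0, np.nan_to_num(p, nan=0.0))


def _subtract(lo, hi, blockers):
    """Pieces of [lo, hi] not covered by sorted disjoint blocker intervals."""
    out = []
    pos = lo
    for bs, be in blockers:
        if be < pos or bs > hi:
            continue
        if bs > pos:
            out.append((pos, min(bs - 1, hi)))
        pos = max(pos, be + 1)
        if pos > hi:
            break
    if pos <= hi:
        out.append((pos, hi))
    return out


def _merge_sorted(iv):
    out = []
    for s, e in sorted(iv):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def simulate_cohort(ann: SimulatedAnnotation, seed: int,
                    n_samples: int | None = None) -> tuple:
    """Generate one cohort's allele-specific segment table plus ground truth.

    Per tumor: candidate HD count ~ Poisson(lambda); candidates accepted by
    clonal survival; accepted HDs merged when overlapping (logged);
    selection-neutral hemizygous events added; every chromosome arm tiled
    with the diploid (1,1) background. Deterministic given (config, seed).
    """
    cfg = ann.config
    N = int(n_samples if n_samples is not None else cfg.n_samples)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0407]))
    sampler = _EventSampler(ann)

    n_ev = rng.poisson(cfg.hd_events_per_tumor, N)
    events = sampler.draw_events(rng, int(n_ev.sum()))
    events.insert(0, "sample", np.repeat([f"S{i:05d}" for i in range(N)], n_ev))
    p = sampler.accept_prob(events)
    events["accept_p"] = p
    events["accepted"] = rng.random(len(events)) < p

    n_loh = rng.poisson(cfg.loh_events_per_tumor, N)
    m = int(n_loh.sum())
    # LOH placement is uniform over the genome (selection-neutral); a fraction
    # of events is whole-arm, as arm-level LOH is pervasive in tumor genomes
    ci = rng.integers(0, cfg.n_chromosomes, m)
    L = sampler.chrom_len[ci]
    start = 1 + np.floor(rng.random(m) * L).astype(np.int64)
    cs, ce = sampler.cen[ci, 0], sampler.cen[ci, 1]
    in_gap = (start >= cs) & (start <= ce)
    start[in_gap] = np.maximum(1, cs[in_gap] - 1)
    length = np.maximum(1, rng.exponential(cfg.loh_mean_length_mb * MB, m)).astype(np.int64)
    end = np.minimum(start + length - 1, np.where(start < cs, cs - 1, L))
    whole_arm = rng.random(m) < cfg.loh_whole_arm_fraction
    q_arm = rng.random(m) < 0.5
    start[whole_arm] = np.where(q_arm[whole_arm], ce[whole_arm] + 1, 1)
    end[whole_arm] = np.where(q_arm[whole_arm], L[whole_arm], cs[whole_arm] - 1)
    loh = pd.DataFrame({
        "sample": np.repeat([f"S{i:05d}" for i in range(N)], n_loh),
        "chrom": sampler.chrom_names[ci], "start": start, "end": end,
        "neutral": rng.random(m) < cfg.loh_copy_neutral_fraction,
    })

    emit = events[events["accepted"] & (events["end"] >= events["start"])]
    segments = _emit_segments(ann.layout, emit, loh, N)
    truth = SimulatedTruth(
        events=events.drop(columns="ci"),
        per_gene=pd.DataFrame({
            "gene_id": ann.genes["gene_id"],
            "class": _gene_class(ann.annotations["is_driver"].to_numpy(),
                                 ann.annotations["is_tsg"].to_numpy(),
                                 ann.annotations["essential_truth"].to_numpy(),
                                 ann.annotations["is_paralog"].to_numpy()),
            "survival": ann.survival.to_numpy(),
        }),
        seed=int(seed), config_digest=cfg.digest())
    return segments, truth


def _emit_segments(layout: GenomeLayout, hd: pd.DataFrame, loh: pd.DataFrame,
                   n_samples: int) -> pd.DataFrame:
    """Tile every chromosome arm of every sample with HD / LOH / (1,1) rows."""
    chroms = layout.chromosomes
    arms = {c: ((1, layout.centromeres[c][0] - 1),
                (layout.centromeres[c][1] + 1, layout.chrom_lengths[c]))
            for c in chroms}
    hd_by = {k: g for k, g in hd.groupby(["sample", "chrom"], sort=False)}
    loh_by = {k: g for k, g in loh.groupby(["sample", "chrom"], sort=False)}
    n_merged_overlap = 0
    samples = [f"S{i:05d}" for i in range(n_samples)]
    recs_sample, recs_chrom = [], []
    recs_start, recs_end, recs_maj, recs_min = [], [], [], []

    def put(s, c, a, b, ma, mi):
        recs_sample.append(s); recs_chrom.append(c)
        recs_start.append(a); recs_end.append(b)
        recs_maj.append(ma); recs_min.append(mi)

    for s in samples:
        for c in chroms:
            hdi = hd_by.get((s, c))
            lohi = loh_by.get((s, c))
            if hdi is None and lohi is None:
                for a1, a2 in arms[c]:
                    put(s, c, a1, a2, 1, 1)
                continue
            hd_iv = _merge_sorted(list(zip(hdi["start"], hdi["end"]))) if hdi is not None else []
            if hdi is not None and len(hd_iv) < len(hdi):
                n_merged_overlap += len(hdi) - len(hd_iv)
            loh_iv = []
            if lohi is not None:
                taken = list(hd_iv)
                for r in lohi.sort_values("start").itertuples():
                    pieces = _subtract(int(r.start), int(r.end), _merge_sorted(taken))
                    cn = 2 if r.neutral else 1
                    for a, b in pieces:
                        loh_iv.append((a, b, cn))
                        taken.append((a, b))
                    taken = _merge_sorted(taken)
            for a1, a2 in arms[c]:
                marks = ([(max(a, a1), min(b, a2), 0, 0) for a, b in hd_iv if b >= a1 and a <= a2]
                         + [(max(a, a1), min(b, a2), cn, 0) for a, b, cn in loh_iv
                            if b >= a1 and a <= a2])
                marks.sort()
                pos = a1
                for a, b, ma, mi in marks:
                    if a > pos:
                        put(s, c, pos, a - 1, 1, 1)
                    put(s, c, a, b, ma, mi)
                    pos = b + 1
                if pos <= a2:
                    put(s, c, pos, a2, 1, 1)
    if n_merged_overlap:
        logger.info("merged %d overlapping accepted HD events", n_merged_overlap)
    return pd.DataFrame({"sample": recs_sample, "chrom": recs_chrom,
                         "start": np.asarray(recs_start, dtype=np.int64),
                         "end": np.asarray(recs_end, dtype=np.int64),
                         "n_major": np.asarray(recs_maj, dtype=np.int64),
                         "n_minor": np.asarray(recs_min, dtype=np.int64)})


@dataclass
class OracleResult:
    """Expected paralogy enrichment implied by a configuration."""

    or_1plus: float
    or_recurrent: float
    se_log_or_1plus: float
    p_hd_by_gene: pd.Series        # per-gene P(>=1 full HD in the cohort)
    n_paralog: int
    n_singleton: int
    method: str


def expected_or_oracle(ann: SimulatedAnnotation, seed: int = 0,
                       n_draws: int = 200_000, recurrent: int = 3,
                       method: str = "mc", grid_step: int = 50_000,
                       n_length_quantiles: int = 64,
                       max_se: float | None = None,
                       n_samples: int | None = None) -> OracleResult:
    """Expected 0 vs 1+ (and 0 vs recurrent+) paralogy odds ratio.

    Computes each gene's per-event probability of being fully deleted by an
    accepted event — by Monte Carlo over the event law (``method='mc'``) or by
    direct enumeration over a start/length grid (``method='grid'``, small
    genomes) — then converts per-sample Poisson event counts into the expected
    cohort 2x2 table over the passenger universe. The standard error of the
    log OR is estimated from Monte Carlo batches; if ``max_se`` is given and
    exceeded, raises prompting more draws.
    """
    cfg = ann.config
    n_cohort = int(n_samples if n_samples is not None else cfg.n_samples)
    sampler = _EventSampler(ann)
    genes = ann.genes
    n_genes = len(genes)

    if method == "mc":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x08AC1E]))
        n_batches = 20
        per_batch = max(1, n_draws // n_batches)
        w_sum = np.zeros(n_genes)
        batch_w = []
        for _ in range(n_batches):
            ev = sampler.draw_events(rng, per_batch)
            p = sampler.accept_prob(ev)
            pairs = map_genes_to_segments(genes, ev, mode="full")
            w = np.zeros(n_genes)
            if not pairs.empty:
                np.add.at(w, pairs["gene_idx"].to_numpy(), p[pairs["seg_idx"].to_numpy()])
            w_sum += w
            batch_w.append(w / per_batch)
        w_g = w_sum / (n_batches * per_batch)
        total_m = n_batches * per_batch
    elif method == "grid":
        # enumerate starts on a grid x exponential-length quantile midpoints
        grid = sampler.grid
        bin_w = np.diff(np.concatenate([[0.0], sampler.cum_w]))
        probs = bin_w / bin_w.sum()
        q = (np.arange(n_length_quantiles) + 0.5) / n_length_quantiles
        w_g = np.zeros(n_genes)
        total_m = 0
        for bi in np.flatnonzero(probs > 0):
            b = grid.iloc[bi]
            ss = np.arange(int(b["start"]), int(b["end"]) + 1, grid_step, dtype=np.int64)
            if not len(ss):
                continue
            frag = False
            arr = sampler.fragile_by_chrom.get(b["chrom"])
            mean_mb = cfg.hd_mean_length_other_mb
            if arr is not None:
                k = np.searchsorted(arr[:, 0], int(b["start"]), side="right") - 1
                if k >= 0 and int(b["start"]) <= arr[k, 1]:
                    mean_mb = cfg.hd_mean_length_fragile_mb
            lens = np.maximum(1, (-mean_mb * MB * np.log(1 - q))).astype(np.int64)
            ci = int(b["ci"])
            cs = sampler.cen[ci, 0]
            for s0 in ss:
                arm_end = cs - 1 if s0 < cs else sampler.chrom_len[ci]
                ends = np.minimum(s0 + lens - 1, arm_end)
                ev = pd.DataFrame({"chrom": b["chrom"], "start": s0, "end": ends})
                p = sampler.accept_prob(ev)
                pairs = map_genes_to_segments(genes, ev, mode="full")
                weight = probs[bi] / (len(ss) * len(lens))
                if not pairs.empty:
                    np.add.at(w_g, pairs["gene_idx"].to_numpy(),
                              weight * p[pairs["seg_idx"].to_numpy()])
        batch_w = None
    else:
        raise SimulationError(f"unknown oracle method {method!r}")

    cls = anno.classify_passengers(genes, ann.annotations.loc[
        ann.annotations["is_driver"], "gene_id"])
    passenger = (cls == "passenger").to_numpy()
    is_par = ann.annotations["is_paralog"].to_numpy()

    def table_from(w):
        lam = cfg.hd_events_per_tumor * w
        q1 = -np.expm1(-lam)                       # P(sample deletes gene)
        p1 = -np.expm1(n_cohort * np.log1p(-np.minimum(q1, 1 - 1e-15)))
        pr = sps.binom.sf(recurrent - 1, n_cohort, q1)
        a1 = p1[passenger & is_par].sum(); n_p = int((passenger & is_par).sum())
        c1 = p1[passenger & ~is_par].sum(); n_s = int((passenger & ~is_par).sum())
        ar = pr[passenger & is_par].sum()
        cr = pr[passenger & ~is_par].sum()
        def _or(a, c, np_, ns_):
            if a <= 0 or c <= 0 or a >= np_ or c >= ns_:
                return np.nan
            return (a / (np_ - a)) / (c / (ns_ - c))
        return (_or(a1, c1, n_p, n_s), _or(ar, cr, n_p, n_s), n_p, n_s, p1)

    or1, orr, n_p, n_s, p1 = table_from(w_g)
    se = np.nan
    if batch_w is not None:
        vals = []
        for w in batch_w:
            o, *_ = table_from(w)
            if np.isfinite(o) and o > 0:
                vals.append(np.log(o))
        if len(vals) > 1:
            se = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
    if max_se is not None and (not np.isfinite(se) or se > max_se):
        raise SimulationError(
            f"oracle Monte Carlo SE {se:.4g} exceeds requested {max_se}; increase n_draws")
    return OracleResult(or_1plus=float(or1), or_recurrent=float(orr),
                        se_log_or_1plus=se,
                        p_hd_by_gene=pd.Series(p1, index=genes["gene_id"]),
                        n_paralog=n_p, n_singleton=n_s, method=method)
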