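"""Synthetic input bundles with planted promoter nucleosome architecture.

The generator emulates the four inputs the pipeline consumes — a gene/TSS
table, per-gene expression (S2 RPKM plus a tissue panel), a chromatin-state
domain map, and two deep nucleosome-site maps (MNase-resistant and
-sensitive) — with the statistical structure the analysis assumes:

* every gene's promoter window sits inside a single state domain, Active
  (Aquamarine / Yellow-Red) with probability ``active_fraction``;
* S2 RPKM follows a class-specific zero-mass + log-normal mixture; the
  tissue panel shares a latent activity with S2 RPKM so breadth of
  expression (BoE) rises with RPKM;
* Active genes carry planted phased nucleosomes (sensitive Nuc-2/Nuc-1 at
  -185/-35, resistant Nuc+1 at +135 plus downstream repeats at 175-nt
  spacing) emitted as many independently jittered site calls, a resistant
  nucleosome-depleted region (NDR) whose depth grows with expression, and
  signed expression->occupancy couplings in fixed offset bands;
* Non-Active genes receive uniformly placed (delocalised) sites with no
  expression coupling.

Occupancy coupling acts through a saturating activity score
``a = min(1, log1p(RPKM) / log1p(rpkm_scale))`` so the dynamic range lies
at low RPKM: planted correlations are recoverable inside the
tissue-specific stratum, while high-RPKM genes saturate (no residual
correlation), as observed for constitutive genes.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import write_bed_domains, write_gene_table, write_table
from .model import (
    ChromatinDomain,
    FILION_MAPPING,
    FOUR_STATE_MAPPING,
    Gene,
    RESISTANT,
    SENSITIVE,
)

_FILLER_STATE = {"4hmm": "Ruby", "filion": "Black"}


@dataclass(frozen=True)
class PeakSpec:
    """One planted nucleosome: TSS-relative offset, mean site calls per gene,
    and the coupling multiplier at activity 0 and 1."""

    sensitivity: str
    offset: int
    calls: float
    coupling: tuple[float, float] = (1.0, 1.0)


@dataclass(frozen=True)
class BandSpec:
    """Uniform site emission over a closed offset band [lo, hi], with a
    per-offset base rate modulated linearly in activity."""

    sensitivity: str
    lo: int
    hi: int
    base_rate: float
    coupling: tuple[float, float] = (1.0, 1.0)


def _default_peaks() -> tuple[PeakSpec, ...]:
    return (
        PeakSpec(SENSITIVE, -185, 40.0, (0.7, 1.3)),  # Nuc-2
        PeakSpec(SENSITIVE, -35, 40.0, (0.7, 1.3)),  # Nuc-1
        PeakSpec(SENSITIVE, 135, 20.0, (0.7, 1.3)),  # sensitive Nuc+1
        PeakSpec(RESISTANT, 135, 60.0, (0.4, 1.6)),  # Nuc+1
        PeakSpec(RESISTANT, 310, 30.0, (0.4, 1.6)),  # Nuc+2 (downstream spacing 175)
        PeakSpec(RESISTANT, 485, 15.0, (0.4, 1.6)),  # Nuc+3
    )


def _default_bands() -> tuple[BandSpec, ...]:
    return (
        BandSpec(RESISTANT, -300, -121, 1.5, (1.0, 1.0)),  # upstream flank, uncoupled
        BandSpec(RESISTANT, -120, 80, 0.8, (2.0, 0.4)),  # NDR: deeper when expressed
        BandSpec(RESISTANT, 70, 200, 1.0, (0.4, 1.6)),  # downstream, positive
        BandSpec(SENSITIVE, -220, -140, 0.5, (0.6, 1.4)),  # upstream ladder, positive
        BandSpec(SENSITIVE, -15, 55, 0.4, (1.5, 0.5)),  # proximal, mildly negative
    )


@dataclass
class SimulationConfig:
    """Defaults define the study conditions every planted-recovery test uses."""

    n_genes: int = 5000
    n_tissues: int = 29
    active_fraction: float = 0.5
    chroms: tuple[str, ...] = ("2L", "2R", "3L", "3R", "X")
    tss_spacing: int = 2000
    chrom_margin: int = 1000
    chrom_length: int | None = None  # derived from packing when None
    state_model: str = "4hmm"
    window: tuple[int, int] = (-300, 200)
    # expression model (zero mass + log-normal, shared latent with tissues)
    active_silent_mass: float = 0.185
    nonactive_silent_mass: float = 0.62
    active_log_mu: float = 1.5
    nonactive_log_mu: float = 0.0
    log_sigma: float = 2.5
    tissue_coupling: float = 0.95
    # nucleosome architecture
    site_length: int = 147
    jitter_sd: float = 15.0
    peaks: tuple[PeakSpec, ...] = field(default_factory=_default_peaks)
    bands: tuple[BandSpec, ...] = field(default_factory=_default_bands)
    rpkm_scale: float = 3.0
    nonactive_resistant_rate: float = 1.3
    nonactive_sensitive_rate: float = 0.35
    background_rate: float = 1e-4  # sites per nt per class, genome-wide

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0.0 <= self.active_fraction <= 1.0):
            raise ValueError("active_fraction must be in [0, 1]")
        if not (0.0 <= self.active_silent_mass <= 1.0):
            raise ValueError("silent mass must be a probability")
        if not (0.0 <= self.nonactive_silent_mass <= 1.0):
            raise ValueError("silent mass must be a probability")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.state_model not in _FILLER_STATE:
            raise ValueError("state_model must be '4hmm' or 'filion'")
        lo, hi = self.window
        for b in self.bands:
            if b.lo > b.hi:
                raise ValueError(f"band [{b.lo}, {b.hi}] is empty")

    @property
    def mapping(self):
        return FOUR_STATE_MAPPING if self.state_model == "4hmm" else FILION_MAPPING

    def activity(self, rpkm: np.ndarray) -> np.ndarray:
        """Saturating expression activity in [0, 1]."""
        return np.minimum(1.0, np.log1p(np.asarray(rpkm, float)) / np.log1p(self.rpkm_scale))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["peaks"] = [dataclasses.asdict(p) for p in self.peaks]
        d["bands"] = [dataclasses.asdict(b) for b in self.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "peaks" in d:
            d["peaks"] = tuple(
                PeakSpec(**{**p, "coupling": tuple(p.get("coupling", (1, 1)))})
                for p in d["peaks"]
            )
        if "bands" in d:
            d["bands"] = tuple(
                BandSpec(**{**b, "coupling": tuple(b.get("coupling", (1, 1)))})
                for b in d["bands"]
            )
        for key in ("chroms", "window"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _chrom_layout(config: SimulationConfig) -> list[tuple[str, int, int]]:
    """(chrom, n_genes_on_chrom, chrom_length) with genes split across arms."""
    n_chrom = len(config.chroms)
    base, extra = divmod(config.n_genes, n_chrom)
    layout = []
    for i, chrom in enumerate(config.chroms):
        n_c = base + (1 if i < extra else 0)
        needed = 2 * config.chrom_margin + n_c * config.tss_spacing
        length = config.chrom_length if config.chrom_length is not None else needed
        if length < needed:
            raise ValueError(
                f"cannot pack {n_c} promoters on {chrom}: need chrom_length >= {needed}"
            )
        layout.append((chrom, n_c, length))
    return layout


def generate_genome(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, list[ChromatinDomain]]:
    """Place TSSs and strands, assign a chromatin state per promoter, and tile
    the genome with state domains.

    Returns a gene table (gene_id, chrom, tss, strand, state; no expression
    yet) and the normalized domain list.  Each promoter's window sits inside
    a single domain of its assigned state; intergenic gaps carry the filler
    (most inert) state.
    """
    rng = np.random.default_rng(seed)
    mapping = config.mapping
    active_states = sorted(mapping.active_states)
    inactive_states = sorted(mapping.inactive_states)
    filler = _FILLER_STATE[config.state_model]
    half = config.window[1] - config.window[0]  # promoter pad on each side
    rows = []
    domains: list[ChromatinDomain] = []
    gid = 0
    for chrom, n_c, length in _chrom_layout(config):
        if n_c == 0:
            continue
        slots = config.chrom_margin + np.arange(n_c) * config.tss_spacing
        jitter_room = max(1, config.tss_spacing - 1000 - 200)
        tss = slots + rng.integers(0, jitter_room, n_c)
        strands = np.where(rng.random(n_c) < 0.5, "+", "-")
        is_active = rng.random(n_c) < config.active_fraction
        states = np.where(
            is_active,
            np.array(active_states)[rng.integers(0, len(active_states), n_c)],
            np.array(inactive_states)[rng.integers(0, len(inactive_states), n_c)],
        )
        prev_end = 0
        for i in range(n_c):
            gid += 1
            rows.append(
                {
                    "gene_id": f"g{gid:05d}",
                    "chrom": chrom,
                    "tss": int(tss[i]),
                    "strand": str(strands[i]),
                    "state": str(states[i]),
                }
            )
            d_start, d_end = int(tss[i]) - half, int(tss[i]) + half
            if d_start > prev_end:
                domains.append(ChromatinDomain(chrom, prev_end, d_start, filler))
            domains.append(ChromatinDomain(chrom, d_start, d_end, str(states[i])))
            prev_end = d_end
        if prev_end < length:
            domains.append(ChromatinDomain(chrom, prev_end, length, filler))
    from .io import normalize_domains

    return pd.DataFrame(rows), normalize_domains(domains)


def generate_expression(
    gene_table: pd.DataFrame, config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Draw S2 RPKM and the tissue RPKM panel for every gene.

    A per-gene latent activity ``u ~ N(0,1)`` drives both: S2 RPKM is 0 when
    u falls below the class's silent quantile and ``exp(mu + sigma u)``
    otherwise; each tissue redraws the latent as
    ``v_t = rho u + sqrt(1-rho^2) e_t`` with the same gating, so BoE grows
    with S2 RPKM for rho > 0 and is independent of it at rho = 0.
    """
    rng = np.random.default_rng(seed)
    n = len(gene_table)
    active = gene_table["state"].isin(config.mapping.active_states).to_numpy()
    mu = np.where(active, config.active_log_mu, config.nonactive_log_mu)
    silent_mass = np.where(
        active, config.active_silent_mass, config.nonactive_silent_mass
    )
    cut = norm.ppf(silent_mass)  # -inf at mass 0, +inf at mass 1
    u = rng.standard_normal(n)
    rpkm_s2 = np.where(u < cut, 0.0, np.exp(mu + config.log_sigma * u))
    rho = config.tissue_coupling
    e = rng.standard_normal((n, config.n_tissues))
    v = rho * u[:, None] + np.sqrt(max(0.0, 1.0 - rho * rho)) * e
    tissues = np.where(
        v < cut[:, None], 0.0, np.exp(mu[:, None] + config.log_sigma * v)
    )
    out = pd.DataFrame({"gene_id": gene_table["gene_id"], "rpkm_s2": rpkm_s2})
    for t in range(config.n_tissues):
        out[f"tissue_{t + 1:02d}"] = tissues[:, t]
    return out


def generate_nucleosomes(
    gene_table: pd.DataFrame,
    expression: pd.DataFrame,
    config: SimulationConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit the resistant and sensitive nucleosome site maps.

    Active genes receive the planted peak architecture and band couplings;
    Non-Active genes receive uniform, expression-independent placement over
    the window; both classes get a uniform genome-wide background.  Sites
    are fixed-length intervals (147 nt) whose centre is the sampled
    position.  Returns two site tables (chrom, start, end), sorted, one per
    sensitivity class.
    """
    rng = np.random.default_rng(seed)
    n = len(gene_table)
    tss = gene_table["tss"].to_numpy(np.int64)
    chrom = gene_table["chrom"].to_numpy()
    sign = np.where(gene_table["strand"].to_numpy() == "+", 1, -1).astype(np.int64)
    active = gene_table["state"].isin(config.mapping.active_states).to_numpy()
    rpkm = (
        expression.set_index("gene_id")
        .loc[gene_table["gene_id"], "rpkm_s2"]
        .to_numpy(float)
    )
    a = config.activity(rpkm)
    half = config.site_length // 2
    lo_w, hi_w = config.window
    parts: dict[str, list[pd.DataFrame]] = {RESISTANT: [], SENSITIVE: []}

    def emit(gene_idx: np.ndarray, offs: np.ndarray, sens: str) -> None:
        centers = tss[gene_idx] + sign[gene_idx] * offs
        start = centers - half
        parts[sens].append(
            pd.DataFrame({"chrom": chrom[gene_idx], "start": start, "end": start + config.site_length})
        )

    # planted peaks (Active genes only), many independently jittered calls each
    for pk in config.peaks:
        m0, m1 = pk.coupling
        lam = np.where(active, pk.calls * (m0 + (m1 - m0) * a), 0.0)
        k = rng.poisson(lam)
        gene_idx = np.repeat(np.arange(n), k)
        jit = np.rint(rng.normal(0.0, config.jitter_sd, k.sum())).astype(np.int64)
        emit(gene_idx, pk.offset + jit, pk.sensitivity)
    # band couplings (Active genes only), uniform within the band
    for bd in config.bands:
        m0, m1 = bd.coupling
        width = bd.hi - bd.lo + 1
        lam = np.where(active, bd.base_rate * width * (m0 + (m1 - m0) * a), 0.0)
        k = rng.poisson(lam)
        gene_idx = np.repeat(np.arange(n), k)
        offs = rng.integers(bd.lo, bd.hi + 1, k.sum())
        emit(gene_idx, offs, bd.sensitivity)
    # Non-Active genes: delocalised, expression-independent placement
    for sens, rate in (
        (RESISTANT, config.nonactive_resistant_rate),
        (SENSITIVE, config.nonactive_sensitive_rate),
    ):
        lam = np.where(active, 0.0, rate * (hi_w - lo_w))
        k = rng.poisson(lam)
        gene_idx = np.repeat(np.arange(n), k)
        offs = rng.integers(lo_w, hi_w, k.sum())
        emit(gene_idx, offs, sens)
    # genome-wide uniform background
    for sens in (RESISTANT, SENSITIVE):
        for chrom_name, _n_c, length in _chrom_layout(config):
            k = rng.poisson(config.background_rate * length)
            centers = rng.integers(half, max(half + 1, length - half - 1), k)
            start = centers - half
            parts[sens].append(
                pd.DataFrame(
                    {"chrom": np.repeat(chrom_name, k), "start": start, "end": start + config.site_length}
                )
            )

    out = []
    for sens in (RESISTANT, SENSITIVE):
        df = pd.concat(parts[sens], ignore_index=True)
        df = df[df["start"] >= 0]
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        out.append(df)
    return out[0], out[1]


def genes_from_tables(
    gene_table: pd.DataFrame, expression: pd.DataFrame
) -> list[Gene]:
    """Materialise Gene records from the generator's tables."""
    tissue_cols = [c for c in expression.columns if c.startswith("tissue_")]
    expr = expression.set_index("gene_id")
    genes = []
    for row in gene_table.itertuples(index=False):
        ex = expr.loc[row.gene_id]
        genes.append(
            Gene(
                gene_id=row.gene_id,
                chrom=row.chrom,
                tss=int(row.tss),
                strand=row.strand,
                rpkm_s2=float(ex["rpkm_s2"]),
                rpkm_tissues=tuple(float(ex[c]) for c in tissue_cols),
            )
        )
    return genes


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def generate_bundle(config: SimulationConfig, outdir: str | os.PathLike, seed: int) -> dict:
    """Write a complete, self-describing input bundle to ``outdir``.

    Files: ``genes.tsv`` (gene table with expression), ``domains.bed``,
    ``resistant.bed``, ``sensitive.bed``, and ``manifest.json`` recording
    the seed, the full config, row counts, and a SHA-256 per file.  Two
    calls with identical (config, seed) produce identical files.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_genome, s_expr, s_nuc = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    gene_table, domains = generate_genome(config, s_genome)
    expression = generate_expression(gene_table, config, s_expr)
    resistant, sensitive = generate_nucleosomes(gene_table, expression, config, s_nuc)

    tissue_cols = [c for c in expression.columns if c != "gene_id"]
    genes_df = pd.concat(
        [gene_table[["gene_id", "chrom", "tss", "strand"]], expression[tissue_cols]],
        axis=1,
    )
    paths = {
        "genes": os.path.join(outdir, "genes.tsv"),
        "domains": os.path.join(outdir, "domains.bed"),
        "resistant": os.path.join(outdir, "resistant.bed"),
        "sensitive": os.path.join(outdir, "sensitive.bed"),
    }
    write_table(genes_df, paths["genes"])
    write_bed_domains(domains, paths["domains"])
    resistant.to_csv(paths["resistant"], sep="\t", header=False, index=False)
    sensitive.to_csv(paths["sensitive"], sep="\t", header=False, index=False)
    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "seed": seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "state_model": config.state_model,
        "n_genes": int(len(genes_df)),
        "n_domains": int(len(domains)),
        "n_resistant_sites": int(len(resistant)),
        "n_sensitive_sites": int(len(sensitive)),
        "files": {name: _sha256(p) for name, p in paths.items()},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def simulate_null_counts(
    n_genes: int, n_offsets: int, seed: int, count_mean: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """A covariate and a count matrix with no dependence between them.

    Counts are deep (Poisson with the given mean), matching the pooled
    site-call depth of the default bundles; the covariate is log-normal.
    Used for Monte-Carlo calibration of the position-wise test.
    """
    rng = np.random.default_rng(seed)
    covariate = rng.lognormal(1.0, 1.5, n_genes)
    counts = rng.poisson(count_mean, (n_genes, n_offsets))
    return covariate, counts
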