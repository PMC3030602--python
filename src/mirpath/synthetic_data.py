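"""Synthetic study generator and packaged table fixtures.

:func:`simulate_study` emulates the full input structure the pipeline
consumes: a two-color miRNA chip (nominally 566 miRNAs, duplicate
hybridizations, several probes per miRNA, log-normal intensities with
probe-level Gaussian noise on the log2 scale and a smooth
intensity-dependent dye bias), probe-level mRNA log2 ratios for two
treated pools over a 20,461-gene array, sparse per-database target
predictions with per-prediction p-values, and a WikiPathways-like GMT
of 117 gene sets.  Planted effects — modulated miRNAs and genes,
guaranteed inverse pairs, and one pathway enriched in both target edges
and modulated genes — carry known ground truth so recovery can be
scored.  Everything is a pure function of (config, seed).

:func:`load_fixtures` returns the packaged transcriptions of the study's
printed summary tables (fold-induction lists, the recurrent-miRNA table,
and the inverse-pair tables), checksum-verified.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
import numpy as np
import pandas as pd

from .data_model import (
    SOURCE_DBS,
    Pathway,
    TimePoint,
    Universe,
    dedupe_predictions,
    write_gmt,
    write_universe,
    _write_tsv,
)
from .normalization import CHANNEL_OVA, CHANNEL_PBS


class FixtureError(RuntimeError):
    """Raised when packaged fixture files fail their checksum."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale and effect-size parameters for the simulator.

    Defaults mirror the nominal study: 566-miRNA chip, 20,461-gene
    array, 117 pathways, planted fold inductions in [1.5, 6], duplicate
    two-channel hybridizations with 8 probes per miRNA and sigma = 0.1
    log2 probe noise.  ``desk()`` returns a shrunken profile (200
    miRNAs, 2,000 genes, 30 pathways) used by the test suite;
    ``null_enrichment()`` keeps the planted differential signals but
    removes every pathway/edge enrichment, which is the null of the
    enrichment stage.
    """

    n_mirnas: int = 566
    n_genes: int = 20461
    n_pathways: int = 117
    pathway_size_range: tuple[int, int] = (20, 100)
    n_modulated_mirnas_per_direction: int = 10
    n_modulated_genes: int = 650
    planted_pathway_count: int = 1
    planted_genes_in_pathway: int = 25
    n_planted_pairs: int = 20
    target_density: float = 0.03
    target_enrichment: float = 8.0
    mirna_fi_range: tuple[float, float] = (1.5, 6.0)
    gene_fi_range: tuple[float, float] = (1.7, 5.0)
    probes_per_mirna: int = 8
    n_replicates: int = 2
    probe_sigma: float = 0.1
    mrna_probe_sigma: float = 0.05
    probes_per_gene_range: tuple[int, int] = (1, 3)
    dye_bias_amplitude: float = 0.2
    background_range: tuple[float, float] = (50.0, 150.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_genes", "n_pathways", "probes_per_mirna",
                     "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.target_density < 1.0):
            raise ValueError("target_density must lie in (0, 1)")
        if self.target_enrichment < 1.0:
            raise ValueError("target_enrichment must be >= 1")
        if 2 * self.n_modulated_mirnas_per_direction > self.n_mirnas:
            raise ValueError("planted miRNA count exceeds the chip universe")
        if self.n_modulated_genes > self.n_genes:
            raise ValueError("planted gene count exceeds the array universe")
        if self.planted_pathway_count and (
            2 * self.planted_genes_in_pathway > self.pathway_size_range[1]
        ):
            raise ValueError(
                "planted_genes_in_pathway too large for the pathway size range"
            )
        if self.planted_pathway_count > self.n_pathways:
            raise ValueError("planted pathway count exceeds the pathway collection")

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Desk-scale profile: 200 miRNAs, 2,000 genes, 30 pathways."""
        base = dict(
            n_mirnas=200,
            n_genes=2000,
            n_pathways=30,
            n_modulated_genes=200,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def null_enrichment(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Desk-scale profile with no pathway/edge enrichment planted."""
        base = dict(planted_pathway_count=0, n_planted_pairs=0)
        base.update(overrides)
        return cls.desk(seed=seed, **base)


@dataclass(frozen=True)
class SimulatedStudy:
    """All pipeline inputs for one simulated study, plus ground truth."""

    config: SimulationConfig
    probe_signals: dict[TimePoint, pd.DataFrame]
    mrna_ratios: dict[TimePoint, pd.DataFrame]
    predictions: dict[str, pd.DataFrame]
    pathways: list[Pathway]
    universe: Universe
    truth: dict

    def write(self, outdir: str | Path, header_comment: str | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tp, df in self.probe_signals.items():
            _write_tsv(df, outdir / f"probe_signals_{tp.name}.tsv", header_comment)
        for tp, df in self.mrna_ratios.items():
            _write_tsv(df, outdir / f"mrna_ratios_{tp.name}.tsv", header_comment)
        for db, df in self.predictions.items():
            _write_tsv(
                df[["mirna_id", "gene_id", "p_value"]],
                outdir / f"predictions_{db}.tsv",
                header_comment,
            )
        write_gmt(self.pathways, outdir / "pathways.gmt")
        write_universe(
            self.universe,
            outdir / "universe.json",
            provenance={"seed": self.config.seed, "preset_n_mirnas": self.config.n_mirnas},
        )
        with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _mirna_ids(n: int) -> np.ndarray:
    return np.array([f"mir-{i:04d}" for i in range(n)])


def _gene_ids(n: int) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(n)])


def _sample_edges(
    rng: np.random.Generator,
    mirnas: np.ndarray,
    genes: np.ndarray,
    density: float,
    p_max: float,
) -> pd.DataFrame:
    """Bernoulli(density) edge sample with prediction p ~ U(0, p_max]."""
    n_m, n_g = len(mirnas), len(genes)
    flat = np.flatnonzero(rng.random(n_m * n_g) < density)
    mi, gi = np.divmod(flat, n_g)
    pvals = p_max * (1.0 - rng.random(flat.size))  # uniform on (0, p_max]
    return pd.DataFrame(
        {"mirna_id": mirnas[mi], "gene_id": genes[gi], "p_value": pvals}
    )


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate every pipeline input with planted, recoverable effects."""
    rng = np.random.default_rng(cfg.seed)
    mirnas = _mirna_ids(cfg.n_mirnas)
    genes = _gene_ids(cfg.n_genes)
    universe = Universe(frozenset(mirnas), frozenset(genes))
    timepoints = list(TimePoint)

    # ---- pathways (the planted ones come first and are sized to hold
    # their planted modulated genes) -----------------------------------
    lo, hi = cfg.pathway_size_range
    pathways: list[Pathway] = []
    planted_pathway_ids = []
    for i in range(cfg.n_pathways):
        if i < cfg.planted_pathway_count:
            size = int(rng.integers(max(lo, 2 * cfg.planted_genes_in_pathway), hi + 1))
        else:
            size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        pid = f"WP{i + 1:03d}"
        pathways.append(Pathway(pid, f"synthetic pathway {i + 1}", frozenset(members)))
        if i < cfg.planted_pathway_count:
            planted_pathway_ids.append(pid)
    planted_pathway_genes = sorted(
        set().union(*(set(pathways[i].genes) for i in range(cfg.planted_pathway_count)))
        if cfg.planted_pathway_count
        else set()
    )

    # ---- per-time-point planted differential signals ------------------
    truth: dict = {
        "planted_pathways": planted_pathway_ids,
        "mirnas": {},
        "genes": {},
        "pairs": {},
    }
    mirna_shift: dict[TimePoint, dict[str, float]] = {}
    gene_shift: dict[TimePoint, dict[str, float]] = {}
    for tp in timepoints:
        n_dir = cfg.n_modulated_mirnas_per_direction
        chosen = rng.choice(mirnas, size=2 * n_dir, replace=False)
        fis = rng.uniform(*cfg.mirna_fi_range, size=2 * n_dir)
        shifts = {}
        up, down = {}, {}
        for j, m in enumerate(chosen):
            sign = 1.0 if j < n_dir else -1.0
            shifts[str(m)] = sign * np.log2(fis[j])
            (up if sign > 0 else down)[str(m)] = float(fis[j] if sign > 0 else 1 / fis[j])
        mirna_shift[tp] = shifts
        truth["mirnas"][tp.name] = {"up": up, "down": down}

        n_in_pw = min(cfg.planted_genes_in_pathway * cfg.planted_pathway_count,
                      len(planted_pathway_genes), cfg.n_modulated_genes)
        in_pw = (
            rng.choice(np.array(planted_pathway_genes), size=n_in_pw, replace=False)
            if n_in_pw
            else np.array([], dtype=object)
        )
        rest_pool = np.array(sorted(set(genes) - set(in_pw)))
        rest = rng.choice(rest_pool, size=cfg.n_modulated_genes - n_in_pw, replace=False)
        chosen_genes = np.concatenate([in_pw, rest])
        gfis = rng.uniform(*cfg.gene_fi_range, size=len(chosen_genes))
        gsigns = np.where(np.arange(len(chosen_genes)) % 2 == 0, 1.0, -1.0)
        gshift = {
            str(g): float(s * np.log2(f))
            for g, s, f in zip(chosen_genes, gsigns, gfis)
        }
        gene_shift[tp] = gshift
        truth["genes"][tp.name] = {
            "up": sorted(g for g, v in gshift.items() if v > 0),
            "down": sorted(g for g, v in gshift.items() if v < 0),
        }

    # ---- miRNA probe signals ------------------------------------------
    base_log2 = rng.normal(10.0, 1.5, size=cfg.n_mirnas)
    probe_affinity = rng.normal(0.0, 0.3, size=(cfg.n_mirnas, cfg.probes_per_mirna))
    probe_signals: dict[TimePoint, pd.DataFrame] = {}
    n_rows = cfg.n_mirnas * cfg.probes_per_mirna
    mir_col = np.repeat(mirnas, cfg.probes_per_mirna)
    probe_col = np.tile(np.arange(cfg.probes_per_mirna), cfg.n_mirnas)
    base_flat = np.repeat(base_log2, cfg.probes_per_mirna) + probe_affinity.ravel()
    for tp in timepoints:
        shift_flat = np.array(
            [mirna_shift[tp].get(m, 0.0) for m in mirnas], dtype=float
        )
        shift_col = np.repeat(shift_flat, cfg.probes_per_mirna)
        frames = []
        for rep in range(1, cfg.n_replicates + 1):
            for channel in (CHANNEL_OVA, CHANNEL_PBS):
                x = base_flat + rng.normal(0.0, cfg.probe_sigma, size=n_rows)
                if channel == CHANNEL_OVA:
                    x = x + shift_col
                else:
                    # smooth, slowly-varying intensity-dependent dye bias on the
                    # control channel (the classic curved MA-plot trend)
                    x = x + cfg.dye_bias_amplitude * np.sin(base_flat / 4.0)
                bg = rng.uniform(*cfg.background_range, size=n_rows)
                frames.append(
                    pd.DataFrame(
                        {
                            "mirna_id": mir_col,
                            "probe_index": probe_col,
                            "replicate": rep,
                            "channel": channel,
                            "raw": 2.0**x + bg,
                            "background": bg,
                        }
                    )
                )
        probe_signals[tp] = pd.concat(frames, ignore_index=True)

    # ---- mRNA probe ratios --------------------------------------------
    plo, phi = cfg.probes_per_gene_range
    probes_per_gene = rng.integers(plo, phi + 1, size=cfg.n_genes)
    gene_col = np.repeat(genes, probes_per_gene)
    probe_ids = np.array([f"probe-{i:06d}" for i in range(gene_col.size)])
    mrna_ratios: dict[TimePoint, pd.DataFrame] = {}
    for tp in timepoints:
        shift = np.array([gene_shift[tp].get(g, 0.0) for g in genes])
        shift_col = np.repeat(shift, probes_per_gene)
        planted_mask = shift_col != 0.0
        sigma = np.where(planted_mask, cfg.mrna_probe_sigma, 0.15)
        pool1 = shift_col + rng.normal(0.0, 1.0, size=gene_col.size) * sigma
        pool2 = shift_col + rng.normal(0.0, 1.0, size=gene_col.size) * sigma
        mrna_ratios[tp] = pd.DataFrame(
            {
                "gene_id": gene_col,
                "probe_id": probe_ids,
                "log_ratio_pool1": pool1,
                "log_ratio_pool2": pool2,
            }
        )

    # ---- target predictions -------------------------------------------
    modulated_union = sorted(
        {m for tp in timepoints for m in mirna_shift[tp].keys()}
    )
    predictions: dict[str, pd.DataFrame] = {}
    for db in SOURCE_DBS:
        parts = [_sample_edges(rng, mirnas, genes, cfg.target_density, 0.05)]
        if cfg.planted_pathway_count and modulated_union:
            extra_density = min(
                1.0, cfg.target_density * (cfg.target_enrichment - 1.0)
            )
            parts.append(
                _sample_edges(
                    rng,
                    np.array(modulated_union),
                    np.array(planted_pathway_genes),
                    extra_density,
                    0.01,
                )
            )
        df = pd.concat(parts, ignore_index=True)
        df["source_db"] = db
        predictions[db] = df

    # ---- guaranteed inverse pairs -------------------------------------
    for tp in timepoints:
        pairs = []
        ups = sorted(truth["mirnas"][tp.name]["up"])
        downs = sorted(truth["mirnas"][tp.name]["down"])
        gups = truth["genes"][tp.name]["up"]
        gdowns = truth["genes"][tp.name]["down"]
        for j in range(cfg.n_planted_pairs):
            if j % 2 == 0 and ups and gdowns:
                pairs.append((ups[(j // 2) % len(ups)], gdowns[j % len(gdowns)]))
            elif downs and gups:
                pairs.append((downs[(j // 2) % len(downs)], gups[j % len(gups)]))
        pairs = sorted(set(pairs))
        truth["pairs"][tp.name] = [list(p) for p in pairs]
        if pairs:
            extra = pd.DataFrame(
                {
                    "mirna_id": [p[0] for p in pairs],
                    "gene_id": [p[1] for p in pairs],
                    "p_value": 0.0005 + 0.0095 * rng.random(len(pairs)),
                }
            )
            for db in SOURCE_DBS:
                add = extra.copy()
                add["source_db"] = db
                predictions[db] = pd.concat([predictions[db], add], ignore_index=True)

    predictions = {db: dedupe_predictions(df) for db, df in predictions.items()}
    return SimulatedStudy(
        config=cfg,
        probe_signals=probe_signals,
        mrna_ratios=mrna_ratios,
        predictions=predictions,
        pathways=pathways,
        universe=universe,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------


def simulate_ct(
    n_assays: int = 14,
    n_mice: int = 6,
    noise_sd: float = 0.15,
    seed: int = 0,
    planted_fc: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a qPCR Ct table (assays x 3 time points x 2 groups x mice).

    OVA-group target Cts are shifted by -log2(planted FC) against a flat
    reference assay (U6), so the comparative-Ct arithmetic recovers the
    planted fold change exactly at zero noise.  Returns (ct_table,
    planted_fc_table); if ``planted_fc`` is not supplied, per-(assay,
    time point) log2 fold changes are drawn uniformly in [-2, 2].
    """
    rng = np.random.default_rng(seed)
    assays = [f"assay-{i:02d}" for i in range(n_assays)]
    tps = [tp.name for tp in TimePoint]
    if planted_fc is None:
        rows = [
            (a, tp, float(2.0 ** rng.uniform(-2.0, 2.0)))
            for a in assays
            for tp in tps
        ]
        planted_fc = pd.DataFrame(rows, columns=["assay_id", "timepoint", "fold_change"])
    fc_map = {
        (r.assay_id, r.timepoint): r.fold_change
        for r in planted_fc.itertuples(index=False)
    }
    baseline = {a: float(rng.uniform(22.0, 30.0)) for a in assays}
    ref_baseline = 18.0
    records = []
    for tp in tps:
        for group in ("PBS", "OVA"):
            for mouse in range(1, n_mice + 1):
                sample = f"{group}-{tp}-m{mouse}"
                records.append(
                    (sample, group, tp, "U6", True,
                     ref_baseline + float(rng.normal(0.0, noise_sd)))
                )
                for a in assays:
                    ct = baseline[a]
                    if group == "OVA":
                        ct -= np.log2(fc_map[(a, tp)])
                    ct += float(rng.normal(0.0, noise_sd))
                    records.append((sample, group, tp, a, False, ct))
    ct = pd.DataFrame(
        records,
        columns=["sample_id", "group", "timepoint", "assay_id", "is_reference", "ct"],
    )
    return ct, planted_fc


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSet:
    """Transcriptions of the study's printed summary tables."""

    table2: pd.DataFrame  # modulated miRNAs with fold inductions per time point
    table3: pd.DataFrame  # miRNAs modulated at >= 2 time points
    table4: pd.DataFrame  # inverse pairs for miRNAs modulated at 2 time points
    table5: pd.DataFrame  # targets of the one miRNA up at all three time points
    notes: dict = field(default_factory=dict)


def _fixture_dir():
    return resources.files("mirpath").joinpath("data/fixtures")


def load_fixtures() -> FixtureSet:
    """Load and checksum-verify the packaged fixture tables."""
    root = _fixture_dir()
    manifest = json.loads(root.joinpath("manifest.json").read_text(encoding="utf-8"))
    frames = {}
    for name, digest in manifest["files"].items():
        raw = root.joinpath(name).read_bytes()
        got = hashlib.sha256(raw).hexdigest()
        if got != digest:
            raise FixtureError(f"fixture {name} checksum mismatch: {got} != {digest}")
        frames[name.split(".")[0]] = pd.read_csv(
            root.joinpath(name).open("r", encoding="utf-8"), sep="\t",
            keep_default_na=False,
        )
    fx = FixtureSet(
        table2=frames["table2"],
        table3=frames["table3"],
        table4=frames["table4"],
        table5=frames["table5"],
        notes=manifest.get("notes", {}),
    )
    if (fx.table2["fold_induction"].astype(float) <= 0).any():
        raise FixtureError("table2 contains non-positive fold inductions")
    return fx


def fixture_measurements(timepoint: TimePoint | None = None):
    """Table 2 rows as MiRnaMeasurement objects (p set just under 0.01).

    The printed table reports only which miRNAs cleared the p < 0.01
    cut, not the p-values themselves, so a nominal passing p is
    attached for membership-rule reconstruction.
    """
    from .data_model import MiRnaMeasurement

    fx = load_fixtures()
    df = fx.table2
    if timepoint is not None:
        df = df[df["timepoint"] == timepoint.name]
    return [
        MiRnaMeasurement(
            r.mirna_id,
            TimePoint.parse(r.timepoint),
            float(r.fold_induction),
            0.009,
        )
        for r in df.itertuples(index=False)
    ]
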