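"""Generators for count tables, yield tables and barcoded reads.

Everything downstream of wet-lab work is testable from these: counts follow
the same Dirichlet-multinomial structure the goodness-of-fit module assumes,
with per-method, per-taxon extraction efficiencies as the bias mechanism;
yields follow a log-scale cell-means model with an experimenter block
effect; reads wrap counts into barcode + linker + primer + template
sequences with substitution errors.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .community_model import MockCommunity, expected_proportions
from .count_processing import CountTable, ReplicateMeta
from .datasets import load_observed_proportion_summary
from .gof_overdispersion import simulate_dm_counts
from .read_qc import AmpliconRead, PrimerSet
from .yield_analysis import YieldTable

__all__ = [
    "SimulationConfig",
    "simulate_counts",
    "reference_count_fixture",
    "simulate_yields",
    "simulate_reads",
    "replicate_layout",
]

_EXPERIMENTERS = ("E1", "E2")
_DAYS = ("D1", "D2")


def replicate_layout(n_replicates: int) -> list[tuple[str, str]]:
    """(experimenter, day) labels cycling two experimenters over two days.

    Eight replicates reproduce the 2 experimenters x 2 days x 2 repeats
    layout: day 1 carries replicates 1-4 (E1, E1, E2, E2), day 2 the rest.
    """
    layout = []
    for j in range(n_replicates):
        day = _DAYS[(j // 4) % 2]
        experimenter = _EXPERIMENTERS[(j // 2) % 2]
        layout.append((experimenter, day))
    return layout


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the generators; see module docstring for the model."""

    community: MockCommunity
    methods: dict[str, np.ndarray] = field(default_factory=dict)  # label -> efficiency
    theta: float = 200.0
    depth: int = 2000
    replicates_per_method: int = 8
    experimenter_sd: float = 0.0
    yield_mean_log: pd.DataFrame | None = None  # sample x method, log µg/ml
    yield_residual_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.community)
        methods = {}
        for label, eff in self.methods.items():
            eff = np.asarray(eff, dtype=float)
            if eff.shape != (k,):
                raise ValueError(
                    f"method {label!r}: efficiency vector must have length {k}"
                )
            if np.any(eff < 0) or not np.all(np.isfinite(eff)):
                raise ValueError(f"method {label!r}: efficiencies must be finite, >= 0")
            methods[label] = eff
        object.__setattr__(self, "methods", methods)
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.replicates_per_method < 1:
            raise ValueError("need at least one replicate")
        if self.experimenter_sd < 0:
            raise ValueError("experimenter_sd must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path, community: MockCommunity) -> "SimulationConfig":
        payload = json.loads(Path(path).read_text())
        methods = {
            label: np.asarray(eff, dtype=float)
            for label, eff in payload.get("methods", {}).items()
        }
        ymeans = payload.get("yield_mean_log")
        ydf = pd.DataFrame(ymeans) if ymeans is not None else None
        return cls(
            community=community,
            methods=methods,
            theta=payload.get("theta", 200.0),
            depth=payload.get("depth", 2000),
            replicates_per_method=payload.get("replicates_per_method", 8),
            experimenter_sd=payload.get("experimenter_sd", 0.0),
            yield_mean_log=ydf,
            yield_residual_sd=payload.get("yield_residual_sd", 0.1),
            seed=payload.get("seed", 0),
        )


def _true_composition(config: SimulationConfig, method: str) -> np.ndarray:
    eff = config.methods.get(method)
    if eff is None:
        raise ValueError(f"method {method!r} not in config")
    weights = (
        config.community.cell_fractions * config.community.copy_numbers * eff
    )
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"method {method!r}: all effective weights are zero")
    return weights / total


def simulate_counts(
    config: SimulationConfig, method: str, seed: int | None = None
) -> CountTable:
    """Dirichlet-multinomial counts for one method.

    True composition is cell_fraction * copy_number * efficiency, normalized;
    each replicate draws proportions ~ Dirichlet(theta * rho) and counts ~
    Multinomial(depth, p).
    """
    rho = _true_composition(config, method)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_rep = config.replicates_per_method
    depths = np.full(n_rep, config.depth, dtype=int)
    counts = simulate_dm_counts(rng, rho, config.theta, depths)
    meta = tuple(
        ReplicateMeta(f"{method}_r{j + 1}", method, exp, day)
        for j, (exp, day) in enumerate(replicate_layout(n_rep))
    )
    return CountTable(config.community.names, counts, meta)


def _largest_remainder_counts(proportions: np.ndarray, depth: int) -> np.ndarray:
    """Integer counts summing exactly to depth, closest to proportions*depth."""
    raw = proportions * depth
    floors = np.floor(raw).astype(np.int64)
    short = depth - int(floors.sum())
    order = np.argsort(-(raw - floors))
    floors[order[:short]] += 1
    return floors


def reference_count_fixture(
    community: MockCommunity,
    depth: int = 2000,
    n_replicates: int = 8,
    seed: int = 0,
) -> dict[str, CountTable]:
    """Reconstructed per-method count tables from the packaged observed
    mean/SD proportion summaries.

    The raw per-replicate reads behind the published summaries are not
    available, so this is a reconstruction: per taxon, replicate proportions
    are the printed mean plus the printed SD times z-scores standardized to
    mean 0 / SD 1 across replicates (so replicate means match the printed
    means exactly before renormalization), clipped at 0, renormalized per
    replicate and converted to counts summing exactly to ``depth``.
    """
    if depth < 100:
        raise ValueError("depth must be >= 100")
    summary = load_observed_proportion_summary()
    rng = np.random.default_rng(seed)
    tables: dict[str, CountTable] = {}
    for method in sorted(summary["method"].unique(), key=str):
        sub = summary[summary["method"] == method].set_index("taxon")
        missing = [t for t in community.names if t not in sub.index]
        if missing:
            raise ValueError(f"summary lacks taxa {missing} for method {method}")
        means = sub.loc[list(community.names), "mean_pct"].to_numpy() / 100.0
        sds = sub.loc[list(community.names), "sd_pct"].to_numpy() / 100.0
        z = rng.standard_normal((len(community), n_replicates))
        z -= z.mean(axis=1, keepdims=True)
        norms = z.std(axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        z /= norms
        props = np.clip(means[:, None] + sds[:, None] * z, 0.0, None)
        props /= props.sum(axis=0, keepdims=True)
        counts = np.column_stack(
            [_largest_remainder_counts(props[:, j], depth) for j in range(n_replicates)]
        )
        label = str(method)
        meta = tuple(
            ReplicateMeta(f"m{label}_r{j + 1}", label, exp, day)
            for j, (exp, day) in enumerate(replicate_layout(n_replicates))
        )
        tables[label] = CountTable(community.names, counts, meta)
    return tables


def simulate_yields(config: SimulationConfig, seed: int | None = None) -> YieldTable:
    """Balanced log-scale yields: cell mean + experimenter block + noise.

    Layout per method x sample: 2 experimenters x 2 days x 2 repeats.
    ``yield_mean_log`` is a sample x method frame of mean log concentrations.
    """
    if config.yield_mean_log is None:
        raise ValueError("config.yield_mean_log is required to simulate yields")
    means = config.yield_mean_log
    rng = np.random.default_rng(config.seed if seed is None else seed)
    block = {e: rng.normal(0.0, config.experimenter_sd) for e in _EXPERIMENTERS}
    records = []
    for method in means.columns:
        for sample in means.index:
            mu = float(means.loc[sample, method])
            rep = 0
            for day in _DAYS:
                for experimenter in _EXPERIMENTERS:
                    for _ in range(2):
                        rep += 1
                        log_conc = (
                            mu
                            + block[experimenter]
                            + rng.normal(0.0, config.yield_residual_sd)
                        )
                        records.append(
                            {
                                "method": str(method),
                                "sample": str(sample),
                                "replicate": rep,
                                "experimenter": experimenter,
                                "day": day,
                                "concentration": float(np.exp(log_conc)),
                            }
                        )
    return YieldTable(pd.DataFrame(records))


def _random_template(rng: np.random.Generator, length: int = 300) -> str:
    # reject templates with long homopolymers so pristine reads pass QC
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        runs = max(
            len(list(g))
            for g in _runs(seq)
        )
        if runs <= 6:
            return seq


def _runs(seq: str):
    run = [seq[0]]
    for ch in seq[1:]:
        if ch == run[-1]:
            run.append(ch)
        else:
            yield run
            run = [ch]
    yield run


_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def simulate_reads(
    config: SimulationConfig,
    counts: CountTable,
    barcodes: dict[str, str],
    primers: PrimerSet,
    error_rate: float = 0.0,
    templates: dict[str, str] | None = None,
    linker: str = "TC",
    seed: int | None = None,
) -> list[AmpliconRead]:
    """One read per count: barcode + linker + primer expansion + template.

    Replicate ids must appear in ``barcodes``.  Substitution errors hit each
    base independently at ``error_rate``.  Ground truth is kept in the read
    id as ``replicate|taxon|serial``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if templates is None:
        templates = {t: _random_template(rng) for t in counts.taxa}
    missing = [r for r in counts.replicate_ids if r not in barcodes]
    if missing:
        raise ValueError(f"no barcode for replicates {missing}")
    primer_list = list(primers.primers.values())
    reads: list[AmpliconRead] = []
    serial = 0
    for j, rid in enumerate(counts.replicate_ids):
        bc = barcodes[rid]
        for i, taxon in enumerate(counts.taxa):
            for _ in range(int(counts.counts[i, j])):
                serial += 1
                primer = primer_list[rng.integers(len(primer_list))]
                primer_concrete = "".join(
                    _IUPAC_CHOICES[c][rng.integers(len(_IUPAC_CHOICES[c]))]
                    for c in primer
                )
                seq = bc + linker + primer_concrete + templates[taxon]
                if error_rate > 0:
                    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                    hit = rng.random(arr.size) < error_rate
                    if hit.any():
                        bases = np.array([b"A", b"C", b"G", b"T"])
                        for pos in np.nonzero(hit)[0]:
                            options = bases[bases != arr[pos]]
                            arr[pos] = options[rng.integers(len(options))]
                    seq = arr.tobytes().decode()
                safe_taxon = taxon.replace("|", "_")
                reads.append(
                    AmpliconRead(
                        f"{rid}|{safe_taxon}|{serial}",
                        seq,
                        tuple([40] * len(seq)),
                    )
                )
    return reads
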