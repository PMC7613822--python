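"""Labeled synthetic inputs for benchmarking every pipeline stage.

The sequence generators emit protein families at controlled percent
identity around planted serine-hydrolase architecture — a G-x-S-x-G
nucleophile motif, downstream catalytic Asp/Glu and His, the gatekeeper
serine after the His, and a class-II cysteine pair — plus triad
knockouts, loop insertions, and composition-preserving shuffled decoys.
The assay generator runs the forward model the quantification math
inverts: product concentrations rise linearly then saturate, the A260
trace is the molar-response-weighted product sum plus Gaussian noise.

Every generator is a pure function of (config, seed): same seed, same
bytes.  All ground truth is recorded in a :class:`SyntheticManifest` so
tests can compare pipeline output against construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .kinetics import AssayTimeSeries, Condition
from .mining import TriadSpec
from .sequence_core import AMINO_ACIDS, ProteinRecord, write_fasta

__all__ = [
    "SyntheticManifest",
    "MetagenomeConfig",
    "AssayConfig",
    "make_reference",
    "mutate_to_identity",
    "plant_insertion",
    "delete_segment",
    "knockout_triad",
    "gen_metagenome",
    "gen_assay",
    "sequence_identity",
]


def sequence_identity(a: str, b: str) -> float:
    """Ungapped position-wise identity of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


@dataclass
class SyntheticManifest:
    """Ground truth for everything a generator emitted."""

    seed: int
    records: dict[str, dict] = field(default_factory=dict)
    assay: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "records": self.records, "assay": self.assay},
                      fh, indent=1, sort_keys=True)

    def family_members(self, family: str) -> list[str]:
        return sorted(
            rid for rid, info in self.records.items()
            if info.get("family") == family and not info.get("decoy")
        )

    def planted_ids(self) -> list[str]:
        return sorted(r for r, i in self.records.items() if not i.get("decoy"))

    def decoy_ids(self) -> list[str]:
        return sorted(r for r, i in self.records.items() if i.get("decoy"))


# ---------------------------------------------------------------------------
# Single-sequence constructors


def make_reference(length: int = 180, seed: int = 0) -> tuple[ProteinRecord, TriadSpec, dict]:
    """A random protein with planted serine-hydrolase architecture.

    Plants the G-x-S-x-G motif around the catalytic serine at ~55% of the
    length, the catalytic Asp and His downstream, a gatekeeper Ser right
    after the His, and the class-II cysteine pair flanking the acid/base
    anchors.  Returns the record, its triad spec, and an extras dict with
    the motif, gatekeeper, and cysteine-pair positions.
    """
    if length < 120:
        raise ValueError("reference length must be >= 120")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(AMINO_ACIDS), size=length))
    ser = int(length * 0.55)
    asp = ser + int(length * 0.16)
    his = asp + int(length * 0.11)
    gate = his + 1
    cys_pair = (asp - 3, his + 2)
    seq[ser - 3], seq[ser - 1] = "G", "S"  # motif G-x-S-x-G, 1-based ser at `ser`
    seq[ser + 1] = "G"
    seq[asp - 1] = "D"
    seq[his - 1] = "H"
    seq[gate - 1] = "S"
    seq[cys_pair[0] - 1] = "C"
    seq[cys_pair[1] - 1] = "C"
    rec = ProteinRecord(f"ref{seed}", "".join(seq), source="synthetic")
    spec = TriadSpec(rec.id, ser, asp, his, reference=rec)
    extras = {
        "motif_span": (ser - 2, ser + 2),
        "gatekeeper_pos": gate,
        "cys_pair": cys_pair,
    }
    return rec, spec, extras


def _protected_positions(spec: TriadSpec, extras: dict) -> set[int]:
    prot = set(range(extras["motif_span"][0], extras["motif_span"][1] + 1))
    prot |= {spec.ser_pos, spec.asp_pos, spec.his_pos, extras["gatekeeper_pos"]}
    prot |= set(extras["cys_pair"])
    return prot


def mutate_to_identity(
    ref: ProteinRecord,
    target_identity: float,
    preserve_positions: Sequence[int] = (),
    seed: int = 0,
    new_id: str | None = None,
) -> ProteinRecord:
    """Substitute random positions until identity hits the target (±0.02).

    Substitutions are uniform over the 19 alternative residues at
    positions outside ``preserve_positions`` (1-based).
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target identity must be in (0, 1]")
    length = len(ref)
    preserve = set(preserve_positions)
    n_mut = round((1.0 - target_identity) * length)
    mutable = [p for p in range(1, length + 1) if p not in preserve]
    if n_mut > len(mutable):
        raise ValueError("target identity incompatible with preserve set")
    rng = np.random.default_rng(seed)
    sites = rng.choice(mutable, size=n_mut, replace=False) if n_mut else []
    seq = list(ref.seq)
    for p in sites:
        current = seq[p - 1]
        alternatives = [a for a in AMINO_ACIDS if a != current]
        seq[p - 1] = alternatives[rng.integers(0, len(alternatives))]
    realized = sequence_identity(ref.seq, "".join(seq))
    if abs(realized - target_identity) > 0.02:
        raise AssertionError(
            f"realized identity {realized:.3f} misses target {target_identity:.3f}"
        )
    return ProteinRecord(new_id or f"{ref.id}_m{seed}", "".join(seq), source="synthetic")


def plant_insertion(
    rec: ProteinRecord, anchor: int, residues: str, new_id: str | None = None
) -> ProteinRecord:
    """Insert residues immediately after 1-based position ``anchor``."""
    if not 0 <= anchor <= len(rec):
        raise ValueError(f"anchor {anchor} outside 0..{len(rec)}")
    seq = rec.seq[:anchor] + residues + rec.seq[anchor:]
    return ProteinRecord(new_id or f"{rec.id}_ins{anchor}", seq, source="synthetic")


def delete_segment(
    rec: ProteinRecord, anchor: int, length: int, new_id: str | None = None
) -> ProteinRecord:
    """Remove ``length`` residues after position ``anchor`` (inverse of plant)."""
    if anchor + length > len(rec):
        raise ValueError("segment extends past sequence end")
    seq = rec.seq[:anchor] + rec.seq[anchor + length :]
    return ProteinRecord(new_id or f"{rec.id}_del{anchor}", seq, source="synthetic")


def knockout_triad(
    rec: ProteinRecord, spec: TriadSpec, which: str, new_id: str | None = None
) -> ProteinRecord:
    """Replace one triad residue with alanine (catalytically dead)."""
    pos = {"ser": spec.ser_pos, "asp": spec.asp_pos, "his": spec.his_pos}.get(which)
    if pos is None:
        raise ValueError("which must be 'ser', 'asp', or 'his'")
    seq = rec.seq[: pos - 1] + "A" + rec.seq[pos:]
    return ProteinRecord(new_id or f"{rec.id}_ko_{which}", seq, source="synthetic")


# ---------------------------------------------------------------------------
# Metagenome benchmark


@dataclass(frozen=True)
class MetagenomeConfig:
    """Shape of the synthetic candidate pool.

    Defaults give three well-separated families (within-family identity
    drawn from 0.6-0.9 against the family reference, i.e. comfortably
    above the 0.4 planted-homolog floor) plus shuffled decoys.
    """

    n_families: int = 3
    members_per_family: int = 5
    identity_range: tuple[float, float] = (0.6, 0.9)
    n_decoys: int = 10
    knockout_fraction: float = 0.0
    ref_length: int = 180

    def __post_init__(self) -> None:
        lo, hi = self.identity_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("identity_range must satisfy 0 < lo <= hi <= 1")
        if not 0 <= self.knockout_fraction <= 1:
            raise ValueError("knockout_fraction must be in [0, 1]")


def gen_metagenome(
    config: MetagenomeConfig = MetagenomeConfig(), seed: int = 0
) -> tuple[list[ProteinRecord], dict, SyntheticManifest]:
    """Synthetic candidate pool: identity-controlled families plus decoys.

    Returns the emitted records (family members and decoys only — family
    references live in the returned ``references`` dict), the references
    (id -> (record, spec, extras)), and the manifest.  The knockout
    fraction is applied deterministically to the first
    ``round(fraction * n_members)`` members of each family, cycling
    through ser/asp/his knockouts.
    """
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    references: dict[str, tuple[ProteinRecord, TriadSpec, dict]] = {}
    manifest = SyntheticManifest(seed=seed)
    lo, hi = config.identity_range
    for f in range(config.n_families):
        ref, spec, extras = make_reference(config.ref_length, seed=seed * 1000 + f)
        fam = f"fam{f}"
        references[ref.id] = (ref, spec, extras)
        protected = sorted(_protected_positions(spec, extras))
        n_ko = round(config.knockout_fraction * config.members_per_family)
        for m in range(config.members_per_family):
            target = float(rng.uniform(lo, hi))
            member = mutate_to_identity(
                ref,
                target,
                preserve_positions=protected,
                seed=int(rng.integers(0, 2**31 - 1)),
                new_id=f"{fam}_m{m}",
            )
            triad_intact = True
            if m < n_ko:
                which = ("ser", "asp", "his")[m % 3]
                member = knockout_triad(member, spec, which, new_id=member.id)
                triad_intact = False
            records.append(member)
            manifest.records[member.id] = {
                "family": fam,
                "reference": ref.id,
                "target_identity": target,
                "realized_identity": sequence_identity(ref.seq, member.seq),
                "triad_intact": triad_intact,
                "insertion": None,
                "decoy": False,
            }
    for d in range(config.n_decoys):
        src_ref, _, _ = references[sorted(references)[d % len(references)]]
        letters = list(src_ref.seq)
        rng.shuffle(letters)
        decoy = ProteinRecord(f"decoy{d}", "".join(letters), source="synthetic")
        records.append(decoy)
        manifest.records[decoy.id] = {
            "family": None,
            "reference": src_ref.id,
            "target_identity": None,
            "realized_identity": sequence_identity(src_ref.seq, decoy.seq),
            "triad_intact": False,
            "insertion": None,
            "decoy": True,
        }
    return records, references, manifest


def write_metagenome(
    records: Sequence[ProteinRecord],
    references: dict,
    manifest: SyntheticManifest,
    outdir: str | Path,
) -> None:
    """Emit candidates.fasta, references.fasta, and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(records, outdir / "candidates.fasta")
    write_fasta([ref for ref, _, _ in references.values()], outdir / "references.fasta")
    manifest.to_json(outdir / "manifest.json")


# ---------------------------------------------------------------------------
# Assay forward model


@dataclass(frozen=True)
class AssayConfig:
    """Forward-model parameters for one synthetic hydrolysis assay.

    Defaults mirror a PET-powder digest read by A260: 500 nM enzyme in
    4 M NaCl at pH 8 and 55 °C, products accumulating linearly for 30 min
    before saturating, molar responses of order 1e-2 absorbance per µM,
    and per-read Gaussian noise.
    """

    tpa_rate: float = 0.8  # µM/min
    mhet_rate: float = 0.5  # µM/min
    eps_tpa: float = 0.017  # A260 per µM
    eps_mhet: float = 0.012  # A260 per µM
    t_sat: float = 30.0  # minutes of linear phase
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 62, 2))
    sigma: float = 0.0
    standard_concs: tuple[float, ...] = tuple(float(c) for c in range(0, 110, 10))
    condition: Condition = Condition(temperature=55.0, nacl=4.0, pH=8.0, enzyme_nm=500.0)

    def product_conc(self, rate: float, t: float) -> float:
        return rate * min(t, self.t_sat)


def gen_assay(
    config: AssayConfig = AssayConfig(), seed: int = 0
) -> tuple[dict[str, list[tuple[float, float]]], AssayTimeSeries, SyntheticManifest]:
    """Standards, an A260 time series, and the manifest of true parameters.

    A260(t) = eps_T * TPA(t) + eps_M * MHET(t) + N(0, sigma); the endpoint
    TPA:MHET molar ratio equals tpa_rate/mhet_rate because both products
    share the same linear-then-saturating time course.
    """
    if config.sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    standards = {
        "TPA": [
            (c, config.eps_tpa * c + float(rng.normal(0, config.sigma)))
            for c in config.standard_concs
        ],
        "MHET": [
            (c, config.eps_mhet * c + float(rng.normal(0, config.sigma)))
            for c in config.standard_concs
        ],
    }
    signal = tuple(
        config.eps_tpa * config.product_conc(config.tpa_rate, t)
        + config.eps_mhet * config.product_conc(config.mhet_rate, t)
        + float(rng.normal(0, config.sigma))
        for t in config.times
    )
    series = AssayTimeSeries(condition=config.condition, times=config.times, signal=signal)
    end = config.times[-1]
    manifest = SyntheticManifest(seed=seed)
    manifest.assay = {
        "tpa_rate": config.tpa_rate,
        "mhet_rate": config.mhet_rate,
        "eps_tpa": config.eps_tpa,
        "eps_mhet": config.eps_mhet,
        "a260_rate_linear": config.eps_tpa * config.tpa_rate
        + config.eps_mhet * config.mhet_rate,
        "endpoint_ratio": (
            config.product_conc(config.tpa_rate, end)
            / config.product_conc(config.mhet_rate, end)
        ),
        "sigma": config.sigma,
        "t_sat": config.t_sat,
        "condition": asdict(config.condition),
    }
    return standards, series, manifest


def write_assay(
    standards: dict[str, list[tuple[float, float]]],
    series: AssayTimeSeries,
    manifest: SyntheticManifest,
    outdir: str | Path,
) -> None:
    """Emit standards.tsv, series.tsv, and manifest.json (unit headers)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "standards.tsv", "w") as fh:
        fh.write("analyte\tconcentration_uM\tsignal\n")
        for analyte, pts in standards.items():
            for c, s in pts:
                fh.write(f"{analyte}\t{c:.6g}\t{s:.8g}\n")
    with open(outdir / "series.tsv", "w") as fh:
        fh.write(
            "temperature_C\tnacl_M\tpH\tenzyme_nM\ttime_min\tsignal_A260\n"
        )
        c = series.condition
        for t, s in zip(series.times, series.signal):
            fh.write(
                f"{c.temperature:.6g}\t{c.nacl:.6g}\t{c.pH:.6g}\t{c.enzyme_nm:.6g}"
                f"\t{t:.6g}\t{s:.8g}\n"
            )
    manifest.to_json(outdir / "manifest.json")
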