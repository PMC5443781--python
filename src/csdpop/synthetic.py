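"""Synthetic csd-like populations: allele pools, colonies, drones, mutants.

The generator emulates the structure of a maternal-allele survey of honey
bee colonies:

* a pool of distinct alleles, each built as conserved flanks around a
  hypervariable region (HVR) of tandem asparagine/tyrosine-rich repeat
  units of varying length, with occasional single-residue substitutions;
* allele frequencies that are uniform or skewed (geometric or Dirichlet);
* queens heterozygous at the locus, colonies grouped into apiaries, with a
  configurable chance that a colony shares its queen's genotype with a
  sibling colony in the same apiary (swarms staying where they emerged);
* slippage-like mutation replacing a queen allele with a fresh variant
  (one repeat unit inserted or deleted, or one residue substituted) that is
  guaranteed absent from the existing pool — rare, recently generated
  alleles with exact ground truth;
* haploid drones, each carrying one maternal allele with probability 1/2.

Every sequence can be written back to nucleotide FASTA with fixed codons
(N -> AAT, Y -> TAT, mirroring the A/T-rich repeat structure of the real
locus) so the reading/translation stage can be exercised end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .sequences import AlleleRecord, write_fasta

__all__ = [
    "SimConfig",
    "TruthTable",
    "AlleleTruth",
    "make_allele_pool",
    "simulate_population",
    "maternal_observations",
    "snapshot_reference",
    "back_translate",
    "write_outputs",
]

FreqModel = Literal["uniform", "geometric", "dirichlet"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic population.

    Defaults mirror the scale of the surveyed Polish populations: a pool of
    133 distinct alleles (the pooled-survey richness estimate), 18 apiaries
    of 11 colonies (198 colonies against the study's 193), 6 drones per
    colony.  ``mutation_prob`` defaults to 0.02 per queen allele, the high
    end of published per-generation slippage rates for microsatellite-like
    tracts, so rare novel alleles are present but scarce.
    """

    n_alleles: int = 133
    freq_model: FreqModel = "uniform"
    freq_param: float = 0.9  # geometric ratio r, or Dirichlet concentration
    n_apiaries: int = 18
    colonies_per_apiary: int = 11
    drones_per_colony: int = 6
    swarm_dup_prob: float = 0.1
    mutation_prob: float = 0.02
    hvr_unit: str = "NY"
    hvr_len_range: tuple[int, int] = (5, 25)
    hvr_subst_rate: float = 0.03  # per-residue substitution prob inside the HVR
    flank_left: str = "RSRERSYG"
    flank_right: str = "PPQSPPSQ"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alleles < 2:
            raise ValueError("need at least 2 alleles (queens are heterozygous)")
        for name in ("swarm_dup_prob", "mutation_prob", "hvr_subst_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        lo, hi = self.hvr_len_range
        if lo < 1 or hi < lo:
            raise ValueError("hvr_len_range must be a positive increasing pair")
        if not self.hvr_unit:
            raise ValueError("hvr_unit must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "hvr_len_range" in raw:
            raw["hvr_len_range"] = tuple(raw["hvr_len_range"])
        return cls(**raw)


@dataclass(frozen=True)
class AlleleTruth:
    aa_seq: str
    frequency: float
    is_mutant: bool


@dataclass
class TruthTable:
    """Ground truth: allele sequences/frequencies and queen genotypes."""

    alleles: dict[str, AlleleTruth] = field(default_factory=dict)
    queens: dict[str, tuple[str, str]] = field(default_factory=dict)

    def mutant_ids(self) -> set[str]:
        return {a for a, t in self.alleles.items() if t.is_mutant}


# substitution alphabet for sprinkled HVR variants; excludes the sentinel
# residue W used by the aligner anchors
_SUBST_ALPHABET = "ACDEFGHIKLMNPQRSTVY"

# one fixed codon per residue; N and Y use the A/T-rich codons of the
# natural repeat
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA",
    "M": "ATG", "N": "AAT", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "TCA", "T": "ACA", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def back_translate(aa_seq: str) -> str:
    """Deterministic nucleotide back-translation with fixed codons."""
    try:
        return "".join(_CODON[res] for res in aa_seq)
    except KeyError as err:
        raise ValueError(f"cannot back-translate residue {err.args[0]!r}") from None


def _frequencies(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_alleles
    if cfg.freq_model == "uniform":
        return np.full(n, 1.0 / n)
    if cfg.freq_model == "geometric":
        w = cfg.freq_param ** np.arange(n)
        return w / w.sum()
    if cfg.freq_model == "dirichlet":
        return rng.dirichlet(np.full(n, cfg.freq_param))
    raise ValueError(f"unknown freq_model {cfg.freq_model!r}")


def _build_hvr(cfg: SimConfig, length: int, rng: np.random.Generator) -> str:
    hvr = list(cfg.hvr_unit * length)
    for i in range(len(hvr)):
        if rng.random() < cfg.hvr_subst_rate:
            hvr[i] = _SUBST_ALPHABET[rng.integers(len(_SUBST_ALPHABET))]
    return "".join(hvr)


def _record(cfg: SimConfig, allele_id: str, hvr: str) -> AlleleRecord:
    aa = cfg.flank_left + hvr + cfg.flank_right
    span = (len(cfg.flank_left), len(cfg.flank_left) + len(hvr))
    return AlleleRecord(id=allele_id, aa_seq=aa, hvr_span=span)


def make_allele_pool(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[AlleleRecord], TruthTable]:
    """Generate a pool of pairwise-distinct alleles with known truth.

    Raises ``ValueError`` when the configured HVR length range cannot host
    ``n_alleles`` distinct sequences within the retry budget.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.hvr_len_range
    seen: set[str] = set()
    records: list[AlleleRecord] = []
    max_tries = 500 * cfg.n_alleles
    tries = 0
    while len(records) < cfg.n_alleles:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "cannot generate "
                f"{cfg.n_alleles} distinct sequences in HVR length range "
                f"{cfg.hvr_len_range}; widen the range or raise hvr_subst_rate"
            )
        length = int(rng.integers(lo, hi + 1))
        hvr = _build_hvr(cfg, length, rng)
        rec = _record(cfg, f"allele_{len(records) + 1:04d}", hvr)
        if rec.aa_seq in seen:
            continue
        seen.add(rec.aa_seq)
        records.append(rec)

    freqs = _frequencies(cfg, rng)
    truth = TruthTable(
        alleles={
            rec.id: AlleleTruth(aa_seq=rec.aa_seq, frequency=float(f), is_mutant=False)
            for rec, f in zip(records, freqs)
        }
    )
    return records, truth


def _slippage_mutant(
    cfg: SimConfig,
    parent: AlleleRecord,
    existing: set[str],
    mutant_id: str,
    rng: np.random.Generator,
) -> AlleleRecord:
    """One slippage event on the parent HVR, collision-checked to be novel."""
    unit = cfg.hvr_unit
    for _ in range(200):
        hvr = parent.hvr_seq
        op = rng.integers(3)
        if op == 0:  # insert one repeat unit
            pos = int(rng.integers(len(hvr) + 1))
            hvr = hvr[:pos] + unit + hvr[pos:]
        elif op == 1 and len(hvr) > len(unit):  # delete one unit's worth
            pos = int(rng.integers(len(hvr) - len(unit) + 1))
            hvr = hvr[:pos] + hvr[pos + len(unit) :]
        else:  # substitute one residue
            pos = int(rng.integers(len(hvr)))
            res = _SUBST_ALPHABET[rng.integers(len(_SUBST_ALPHABET))]
            hvr = hvr[:pos] + res + hvr[pos + 1 :]
        rec = _record(cfg, mutant_id, hvr)
        if rec.aa_seq not in existing:
            return rec
    raise RuntimeError("could not generate a novel mutant after 200 attempts")


def simulate_population(
    cfg: SimConfig,
    pool: list[AlleleRecord],
    truth: TruthTable,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[AlleleRecord], TruthTable]:
    """Simulate queens, colonies, apiaries and drone sampling.

    Returns ``(drones, all_records, truth_out)``: one row per sampled drone
    (columns drone_id, allele_id, apiary_id, colony_id, group_id), the pool
    extended with any slippage mutants, and the truth table with queen
    genotypes filled in.  Apiaries are split into two equal groups ("A"/"B")
    so two-population overlap analyses can be exercised.  Inputs are not
    modified.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    records = list(pool)
    truth_out = TruthTable(alleles=dict(truth.alleles), queens={})
    by_id = {rec.id: rec for rec in records}
    existing_seqs = {rec.aa_seq for rec in records}
    base_ids = [rec.id for rec in pool]
    base_freqs = np.array([truth.alleles[a].frequency for a in base_ids])
    base_freqs = base_freqs / base_freqs.sum()

    n_mutants = 0
    rows = []
    for ai in range(cfg.n_apiaries):
        apiary = f"ap{ai + 1:02d}"
        group = "A" if ai < cfg.n_apiaries // 2 else "B"
        apiary_queens: list[tuple[str, str]] = []
        for ci in range(cfg.colonies_per_apiary):
            colony = f"{apiary}_c{ci + 1:02d}"
            if apiary_queens and rng.random() < cfg.swarm_dup_prob:
                pair = apiary_queens[int(rng.integers(len(apiary_queens)))]
            else:
                while True:
                    a1, a2 = rng.choice(len(base_ids), size=2, p=base_freqs)
                    if base_ids[a1] != base_ids[a2]:
                        break
                pair = (base_ids[a1], base_ids[a2])
                mutated = []
                for allele_id in pair:
                    if rng.random() < cfg.mutation_prob:
                        n_mutants += 1
                        mut = _slippage_mutant(
                            cfg,
                            by_id[allele_id],
                            existing_seqs,
                            f"mutant_{n_mutants:04d}",
                            rng,
                        )
                        records.append(mut)
                        by_id[mut.id] = mut
                        existing_seqs.add(mut.aa_seq)
                        truth_out.alleles[mut.id] = AlleleTruth(
                            aa_seq=mut.aa_seq, frequency=0.0, is_mutant=True
                        )
                        mutated.append(mut.id)
                    else:
                        mutated.append(allele_id)
                pair = (mutated[0], mutated[1])
            apiary_queens.append(pair)
            truth_out.queens[colony] = pair
            for di in range(cfg.drones_per_colony):
                allele = pair[int(rng.integers(2))]
                rows.append(
                    {
                        "drone_id": f"{colony}_d{di + 1}",
                        "allele_id": allele,
                        "apiary_id": apiary,
                        "colony_id": colony,
                        "group_id": group,
                    }
                )
    drones = pd.DataFrame(rows)
    return drones, records, truth_out


def maternal_observations(drones: pd.DataFrame) -> pd.DataFrame:
    """Distinct maternal alleles detected per colony from drone haplotypes.

    This is the unit the survey sequences: each colony contributes the set
    of its queen's alleles that appeared in at least one sampled drone.
    Columns: obs_id, allele_id, apiary_id, colony_id, group_id.
    """
    rows = []
    for colony, group in drones.groupby("colony_id", sort=False):
        seen = pd.unique(group["allele_id"])
        for k, allele in enumerate(seen, start=1):
            rows.append(
                {
                    "obs_id": f"{colony}_m{k}",
                    "allele_id": allele,
                    "apiary_id": group["apiary_id"].iloc[0],
                    "colony_id": colony,
                    "group_id": group["group_id"].iloc[0],
                }
            )
    return pd.DataFrame(rows)


def snapshot_reference(
    pool: list[AlleleRecord],
    truth: TruthTable,
    fraction: float,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Random subset of non-mutant pool alleles as the "already known" set."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    mutants = truth.mutant_ids()
    candidates = [rec for rec in pool if rec.id not in mutants]
    n_keep = int(round(fraction * len(candidates)))
    idx = rng.choice(len(candidates), size=n_keep, replace=False)
    return [candidates[i].aa_seq for i in sorted(idx)]


def write_outputs(
    out_dir: str | Path,
    cfg: SimConfig,
    records: list[AlleleRecord],
    truth: TruthTable,
    observations: pd.DataFrame,
    reference: list[str] | None = None,
) -> dict[str, Path]:
    """Write the simulated dataset as plain-text pipeline inputs.

    Produces nucleotide and amino-acid FASTA of the per-colony maternal
    observations, a sample sheet TSV, the allele truth TSV, the simulation
    config YAML and (optionally) a reference FASTA of "known" alleles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_id = {rec.id: rec for rec in records}
    paths: dict[str, Path] = {}

    obs_aa = [(row.obs_id, by_id[row.allele_id].aa_seq) for row in observations.itertuples()]
    paths["observations_nt"] = out / "observations.nt.fasta"
    write_fasta([(n, back_translate(s)) for n, s in obs_aa], paths["observations_nt"])
    paths["observations_aa"] = out / "observations.aa.fasta"
    write_fasta(obs_aa, paths["observations_aa"])

    sheet = observations.rename(columns={"obs_id": "id"})[
        ["id", "apiary_id", "colony_id", "group_id"]
    ]
    paths["sample_sheet"] = out / "sample_sheet.tsv"
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)

    truth_rows = [
        {
            "allele_id": a,
            "aa_seq": t.aa_seq,
            "frequency": t.frequency,
            "is_mutant": t.is_mutant,
        }
        for a, t in truth.alleles.items()
    ]
    paths["truth"] = out / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)

    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["hvr_len_range"] = list(cfg.hvr_len_range)
    paths["config"] = out / "sim_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)

    if reference is not None:
        paths["reference"] = out / "reference.aa.fasta"
        write_fasta(
            [(f"ref_{i + 1:04d}", s) for i, s in enumerate(reference)],
            paths["reference"],
        )
    return paths
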