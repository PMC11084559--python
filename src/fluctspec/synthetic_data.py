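"""Synthetic fluctuation-assay studies with known ground truth.

Emulates the design of a two-strain, two-glucose rifampicin fluctuation
experiment: 182 parallel cultures per condition with Luria–Delbrück
mutant counts, final population sizes estimated from 3 replicate CFU
platings (lognormal noise), and Sanger-style reads of the rpoB RRDR
window for isolated resistant mutants, ~78% of which carry one planted
cluster I/II mutation drawn from a condition-dependent 8-category
spectrum.

The shipped reference CDS is synthetic: a deterministic random 4029-nt
open reading frame with the real gene's length, codon structure and
printed RRDR coordinates, not the NC_000913.3 sequence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .luria_delbruck import LDParams, simulate_counts
from .rpob_calls import RRDR_CLUSTERS, Reference
from .spectrum_models import CATEGORIES, SNV_CLASSES, SpectrumTable

__all__ = [
    "ConditionConfig",
    "StudyConfig",
    "TruthRecord",
    "default_study",
    "synthetic_reference",
    "gen_fluctuation_study",
    "gen_isolate_reads",
    "gen_spectrum_counts",
    "load_config_toml",
]

RPOB_CDS_LENGTH = 4029  # printed genomic window 4181245..4185273
_STOPS = {"TAA", "TAG", "TGA"}

# Mutant base implied by each SNV class, given the reference base
_ALT_FOR = {
    "AT>GC": {"A": "G", "T": "C"},
    "GC>AT": {"G": "A", "C": "T"},
    "AT>CG": {"A": "C", "T": "G"},
    "AT>TA": {"A": "T", "T": "A"},
    "GC>CG": {"G": "C", "C": "G"},
    "GC>TA": {"G": "T", "C": "A"},
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ConditionConfig:
    """Ground-truth parameters for one strain x glucose condition."""

    strain: str
    glucose: str
    m_true: float
    fitness_true: float = 1.0
    nt_true: float = 1e8
    n_cultures: int = 182
    n_cfu_replicates: int = 3
    cfu_noise_cv: float = 0.10
    spectrum_probs: tuple = ()
    n_isolates: int = 68

    @property
    def mu_true(self) -> float:
        return self.m_true / self.nt_true

    def __post_init__(self) -> None:
        probs = np.asarray(self.spectrum_probs, dtype=float)
        if probs.size != len(CATEGORIES):
            raise ValueError("spectrum_probs must have 8 entries")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("spectrum_probs must sum to 1")
        if self.m_true < 0 or self.nt_true <= 0 or self.fitness_true <= 0:
            raise ValueError("rates and sizes must be positive")


@dataclass(frozen=True)
class StudyConfig:
    """Full synthetic-study configuration (pure function of seed)."""

    conditions: tuple
    read_window: tuple = (1400, 1900)
    read_error_rate: float = 0.0
    detection_prob: float = 214.0 / 274.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.detection_prob <= 1.0):
            raise ValueError("detection_prob must be in [0, 1]")
        if not (0.0 <= self.read_error_rate < 1.0):
            raise ValueError("read_error_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth for one generated study."""

    conditions: dict = field(default_factory=dict)  # (strain,glucose) -> m/mu
    isolates: dict = field(default_factory=dict)  # isolate_id -> planted mutation

    def to_json(self, path) -> None:
        payload = {
            "conditions": {f"{s}|{g}": v for (s, g), v in self.conditions.items()},
            "isolates": self.isolates,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# Default scenario: wild-type responds to glucose (low-to-high rate ratio
# 1.6), the deletant barely does (1.06) because a GC>TA increase under
# high glucose offsets the AT>GC decrease.  Spectrum probabilities follow
# that motif: AT>GC enriched at low glucose in both strains, GC>TA
# enriched in the deletant and more so at high glucose.
_DEFAULT_SPECTRA = {
    ("MG1655", "low"): (0.45, 0.13, 0.10, 0.10, 0.03, 0.08, 0.05, 0.06),
    ("MG1655", "high"): (0.25, 0.18, 0.12, 0.13, 0.04, 0.14, 0.06, 0.08),
    ("luxS", "low"): (0.45, 0.12, 0.10, 0.10, 0.03, 0.14, 0.03, 0.03),
    ("luxS", "high"): (0.25, 0.15, 0.11, 0.12, 0.03, 0.26, 0.04, 0.04),
}

_DEFAULT_M = {("MG1655", "low"): 1.6, ("MG1655", "high"): 1.0,
              ("luxS", "low"): 1.06, ("luxS", "high"): 1.0}
_DEFAULT_N_ISOLATES = {("MG1655", "low"): 75, ("MG1655", "high"): 62,
                       ("luxS", "low"): 68, ("luxS", "high"): 69}


def default_study(seed: int = 0, **overrides) -> StudyConfig:
    """The default two-strain, two-glucose scenario."""
    conditions = tuple(
        ConditionConfig(strain=s, glucose=g, m_true=_DEFAULT_M[(s, g)],
                        spectrum_probs=_DEFAULT_SPECTRA[(s, g)],
                        n_isolates=_DEFAULT_N_ISOLATES[(s, g)])
        for s, g in _DEFAULT_SPECTRA
    )
    return StudyConfig(conditions=conditions, seed=seed, **overrides)


def synthetic_reference(seed: int = 20240430) -> Reference:
    """Deterministic synthetic rpoB CDS stand-in.

    4029 nt (1343 codons), ATG start, TAA stop, no internal stop codons;
    anchored at the printed genomic window so CDS position 1 maps to
    genomic 4181245.  This is not the real NC_000913.3 sequence.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    codons = ["ATG"]
    while len(codons) < RPOB_CDS_LENGTH // 3 - 1:
        codon = "".join(rng.choice(bases, 3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append("TAA")
    return Reference(gene_id="rpoB", cds_sequence="".join(codons),
                     genome_accession="NC_000913.3", genome_offset=4181245)


def gen_fluctuation_study(config: StudyConfig):
    """Generate mutant-count and CFU tables for every condition.

    Returns (counts_df, cfu_df, truth): counts_df has one row per parallel
    culture; cfu_df one row per replicate plating, lognormal around
    nt_true with the configured CV.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthRecord()
    count_rows, cfu_rows = [], []
    for cond in config.conditions:
        sub_seed = int(rng.integers(2**31))
        counts = simulate_counts(cond.n_cultures,
                                 LDParams(cond.m_true, cond.fitness_true),
                                 seed=sub_seed)
        for i, c in enumerate(counts, start=1):
            count_rows.append(dict(strain=cond.strain, glucose=cond.glucose,
                                   culture_id=i, mutant_count=int(c)))
        cv = cond.cfu_noise_cv
        sigma = np.sqrt(np.log1p(cv * cv))
        mu_log = np.log(cond.nt_true) - sigma**2 / 2  # mean-preserving
        cfu = rng.lognormal(mu_log, sigma, size=cond.n_cfu_replicates)
        for j, v in enumerate(cfu, start=1):
            cfu_rows.append(dict(strain=cond.strain, glucose=cond.glucose,
                                 replicate=j, cfu_total=float(v)))
        truth.conditions[(cond.strain, cond.glucose)] = {
            "m_true": cond.m_true, "mu_true": cond.mu_true,
            "nt_true": cond.nt_true,
        }
    return pd.DataFrame(count_rows), pd.DataFrame(cfu_rows), truth


def _candidate_sites(ref: Reference, category: str) -> list:
    """CDS positions in clusters I/II where the category can be planted."""
    cds = ref.cds_sequence
    sites = []
    for lo, hi in (RRDR_CLUSTERS["I"], RRDR_CLUSTERS["II"]):
        for pos in range(lo, hi + 1):
            if category in _ALT_FOR and cds[pos - 1] in _ALT_FOR[category]:
                sites.append(pos)
    if category == "insertion":
        # in-frame codon duplications at codon boundaries inside cluster I
        lo, hi = RRDR_CLUSTERS["I"]
        sites = [p for p in range(lo, hi - 2) if p % 3 == 1]
    elif category == "deletion":
        lo, hi = RRDR_CLUSTERS["I"]
        sites = [p for p in range(lo, hi - 2) if p % 3 == 1]
    return sites


def _plant_mutation(window_seq: str, window_start: int, cds: str,
                    category: str, pos: int):
    """Apply one mutation of the given category at CDS position pos."""
    i = pos - window_start  # 0-based index into the window
    if category in _ALT_FOR:
        ref_b = window_seq[i]
        alt_b = _ALT_FOR[category][ref_b]
        mutated = window_seq[:i] + alt_b + window_seq[i + 1 :]
        return mutated, {"cds_pos": pos, "ref": ref_b, "alt": alt_b,
                         "category": category, "kind": "substitution"}
    if category == "deletion":
        deleted = window_seq[i : i + 3]
        mutated = window_seq[:i] + window_seq[i + 3 :]
        return mutated, {"cds_pos": pos, "ref": deleted, "alt": "",
                         "category": category, "kind": "deletion"}
    # insertion: duplicate the codon starting at pos
    dup = cds[pos - 1 : pos + 2]
    mutated = window_seq[: i + 3] + dup + window_seq[i + 3 :]
    return mutated, {"cds_pos": pos, "ref": "", "alt": dup,
                     "category": category, "kind": "insertion"}


def gen_isolate_reads(config: StudyConfig, ref: Reference,
                      site_lists: dict | None = None):
    """Generate mutant rpoB reads with planted RRDR mutations.

    Returns (records, metadata_df, truth).  ``records`` is a list of
    (isolate_id, sequence).  With probability ``detection_prob`` an
    isolate carries one mutation in the sequenced window, drawn from its
    condition's category probabilities at a compatible cluster I/II site;
    otherwise its read matches the reference.  Uniform base errors are
    added at ``read_error_rate`` and strand orientation is random.
    """
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.read_window
    cds = ref.cds_sequence
    window = cds[lo - 1 : hi]
    sites = {cat: (site_lists or {}).get(cat) or _candidate_sites(ref, cat)
             for cat in CATEGORIES}
    records, meta_rows = [], []
    truth = TruthRecord()
    counter = 0
    for cond in config.conditions:
        probs = np.asarray(cond.spectrum_probs)
        for cat, p in zip(CATEGORIES, probs):
            if p > 0 and not sites[cat]:
                raise ValueError(f"no compatible site for category {cat}")
        for _ in range(cond.n_isolates):
            counter += 1
            iso = f"iso{counter:04d}"
            detected = rng.random() < config.detection_prob
            if detected:
                cat = CATEGORIES[rng.choice(len(CATEGORIES), p=probs)]
                pos = int(sites[cat][rng.integers(len(sites[cat]))])
                seq, plant = _plant_mutation(window, lo, cds, cat, pos)
            else:
                seq, plant = window, None
            if config.read_error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
                hit = rng.random(arr.size) < config.read_error_rate
                for idx in np.nonzero(hit)[0]:
                    others = [b for b in "ACGT" if b != arr[idx]]
                    arr[idx] = others[rng.integers(3)]
                seq = "".join(arr)
            if rng.random() < 0.5:
                seq = seq.translate(_COMPLEMENT)[::-1]
            records.append((iso, seq))
            meta_rows.append(dict(isolate_id=iso, strain=cond.strain,
                                  glucose=cond.glucose))
            truth.isolates[iso] = plant
    return records, pd.DataFrame(meta_rows), truth


def gen_spectrum_counts(config: StudyConfig) -> tuple[SpectrumTable, TruthRecord]:
    """Draw category counts directly (multinomial), bypassing reads."""
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    truth = TruthRecord()
    for cond in config.conditions:
        counts = rng.multinomial(cond.n_isolates, np.asarray(cond.spectrum_probs))
        for cat, c in zip(CATEGORIES, counts):
            rows.append(dict(category=cat, strain=cond.strain,
                             glucose=cond.glucose, count=int(c)))
        truth.conditions[(cond.strain, cond.glucose)] = {
            "spectrum_probs": list(cond.spectrum_probs),
            "n_isolates": cond.n_isolates,
        }
    return SpectrumTable.from_long(pd.DataFrame(rows)), truth


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def load_config_toml(path) -> StudyConfig:
    """Load a StudyConfig from a TOML file.

    Layout: top-level keys mirror StudyConfig fields; each
    [[conditions]] table mirrors ConditionConfig.
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    conds = tuple(ConditionConfig(**{**c, "spectrum_probs": tuple(c["spectrum_probs"])})
                  for c in raw.pop("conditions"))
    if "read_window" in raw:
        raw["read_window"] = tuple(raw["read_window"])
    return StudyConfig(conditions=conds, **raw)
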