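"""Synthetic data generation with known ground truth.

Emulates the structure of a 6-plex TMT lysine-crotonylation (Kcr)
experiment: a searched protein database, tryptic peptides, Kcr sites with
flanking windows and localization probabilities, log-normal reporter-ion
intensities with separable protein-level and site-level treatment effects,
planted flanking-sequence motifs, and per-species ortholog proteomes with
controlled lysine retention. Every stochastic choice flows through an
explicit seed, and the generator records the truth it planted so that
downstream estimates can be checked against it exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_AA_SET = set(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One entry of a searched protein database."""

    protein_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: non-standard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class ChannelDesign:
    """Ordered 6-plex reporter channel layout: 3 control (CK) + 3 treatment (T)."""

    channel_labels: tuple[str, ...]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        groups = [self.group_of[c] for c in self.channel_labels]
        if groups.count("CK") != 3 or groups.count("T") != 3:
            raise ValueError(
                "design must have exactly 3 CK and 3 T channels, got "
                f"{groups}"
            )

    @classmethod
    def default(cls) -> "ChannelDesign":
        labels = ("CK-01", "CK-02", "CK-03", "T-01", "T-02", "T-03")
        return cls(labels, {c: ("CK" if c.startswith("CK") else "T") for c in labels})

    def channels(self, group: str) -> list[str]:
        return [c for c in self.channel_labels if self.group_of[c] == group]


@dataclass(frozen=True)
class MotifSpec:
    """A planted motif: residue constraints at signed offsets around the Kcr.

    Offsets are relative to the modified lysine (0 excluded: the center is
    the K itself); prevalence is the probability a planted site carries the
    motif.
    """

    constraints: tuple[tuple[int, str], ...]
    prevalence: float

    def __post_init__(self) -> None:
        for off, res in self.constraints:
            if off == 0:
                raise ValueError("motif offset 0 is the modified K itself")
            if not -10 <= off <= 10:
                raise ValueError(f"motif offset {off} outside [-10, +10]")
            if res not in _AA_SET:
                raise ValueError(f"motif residue {res!r} is not a standard amino acid")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery tests.

    ``retention`` records, per species and per lysine column of the source
    proteome, whether that lysine was kept in the simulated ortholog —
    conservation counting downstream must reproduce these draws exactly.
    """

    protein_effects: dict[str, float] = field(default_factory=dict)
    site_effects: dict[tuple[str, int], float] = field(default_factory=dict)
    planted_motifs: list[MotifSpec] = field(default_factory=list)
    conservation_rates: dict[str, tuple[float, float]] = field(default_factory=dict)
    motif_assignment: dict[tuple[str, int], int] = field(default_factory=dict)
    retention: dict[str, dict[tuple[str, int], tuple[bool, bool]]] = field(
        default_factory=dict
    )


@dataclass(frozen=True)
class PeptideTemplate:
    """A digested peptide placed in its protein (0-based start)."""

    protein_id: str
    sequence: str
    start: int
    is_unique: bool = True


# ---------------------------------------------------------------------------
# Proteome generation and digestion
# ---------------------------------------------------------------------------

def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (100, 600),
    residue_frequencies: np.ndarray | None = None,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Draw random protein sequences with i.i.d. residues.

    ``residue_frequencies`` follows the alphabetical order of
    ``AMINO_ACIDS``; it must sum to 1.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if not (30 <= lo <= hi <= 5000):
        raise ValueError("length_range must satisfy 30 <= lo <= hi <= 5000")
    if residue_frequencies is None:
        freqs = np.full(20, 1.0 / 20.0)
    else:
        freqs = np.asarray(residue_frequencies, dtype=float)
        if freqs.shape != (20,):
            raise ValueError("residue_frequencies must have 20 entries")
        total = float(freqs.sum())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(
                f"residue frequencies sum to {total!r}, deviating from 1 by "
                f"{total - 1.0:+.3g}"
            )
    rng = np.random.default_rng(seed)
    width = len(str(n_proteins))
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(np.array(list(AMINO_ACIDS))[rng.choice(20, size=length, p=freqs)])
        records.append(
            ProteinRecord(f"SYN{i + 1:0{width}d}", seq, "synthetic protein")
        )
    return records


_TRYPTIC_RE = re.compile(r".*?[KR](?!P)|.+?$")


def digest_tryptic(
    protein: ProteinRecord, min_len: int = 7, max_len: int = 50
) -> list[tuple[str, int]]:
    """In-silico tryptic digestion: cleave after K/R except before P.

    Returns ``(peptide, start)`` with 0-based start positions; peptides
    outside ``[min_len, max_len]`` are discarded after cleavage. No missed
    cleavages are generated.
    """
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    out = []
    pos = 0
    for m in _TRYPTIC_RE.finditer(protein.sequence):
        pep = m.group(0)
        if min_len <= len(pep) <= max_len:
            out.append((pep, pos))
        pos += len(pep)
    return out


def digest_proteome(
    proteins: list[ProteinRecord], min_len: int = 7, max_len: int = 50
) -> list[PeptideTemplate]:
    """Digest every protein and mark peptides unique to a single protein."""
    raw: list[tuple[str, str, int]] = []
    owners: dict[str, set[str]] = {}
    for prot in proteins:
        for pep, start in digest_tryptic(prot, min_len, max_len):
            raw.append((prot.protein_id, pep, start))
            owners.setdefault(pep, set()).add(prot.protein_id)
    return [
        PeptideTemplate(pid, pep, start, is_unique=len(owners[pep]) == 1)
        for pid, pep, start in raw
    ]


# ---------------------------------------------------------------------------
# Site and motif planting
# ---------------------------------------------------------------------------

def plant_sites_and_motifs(
    proteins: list[ProteinRecord],
    site_fraction: float,
    motif_specs: list[MotifSpec] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[tuple[str, int]], GroundTruth]:
    """Select Kcr sites over lysines and stamp motif residues around them.

    Each lysine becomes a site independently with probability
    ``site_fraction``. Each site then carries motif *i* with probability
    ``motif_specs[i].prevalence`` (prevalences must sum to <= 1); carrying a
    motif rewrites the flanking residues at the constrained offsets, so the
    returned proteome differs from the input. A motif is skipped for a site
    whose protein is too short for a constrained offset, or where an edit
    would overwrite another selected site's central K; such sites stay plain.

    Returns the (possibly edited) proteome, the site list as 1-based
    ``(protein_id, position)`` pairs, and a :class:`GroundTruth` recording
    which motif (index) each site carries.
    """
    motif_specs = list(motif_specs or [])
    if sum(m.prevalence for m in motif_specs) > 1.0 + 1e-12:
        raise ValueError("motif prevalences must sum to <= 1")
    if not 0.0 <= site_fraction <= 1.0:
        raise ValueError("site_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = GroundTruth(planted_motifs=motif_specs)
    sites: list[tuple[str, int]] = []
    sequences = {p.protein_id: list(p.sequence) for p in proteins}

    # choose sites first so motif edits can avoid other sites' centers
    site_set: set[tuple[str, int]] = set()
    for prot in proteins:
        for idx, res in enumerate(prot.sequence):
            if res == "K" and rng.random() < site_fraction:
                site_set.add((prot.protein_id, idx + 1))

    prevs = np.array([m.prevalence for m in motif_specs])
    for prot in proteins:
        seq = sequences[prot.protein_id]
        for pos1 in sorted(p for pid, p in site_set if pid == prot.protein_id):
            key = (prot.protein_id, pos1)
            sites.append(key)
            midx = -1
            if motif_specs:
                u = rng.random()
                cum = np.cumsum(prevs)
                hit = np.searchsorted(cum, u, side="right")
                if hit < len(motif_specs) and u < cum[-1]:
                    midx = int(hit)
            if midx >= 0:
                spec = motif_specs[midx]
                targets = [(pos1 - 1 + off, res) for off, res in spec.constraints]
                ok = all(
                    0 <= t < len(seq)
                    and not ((prot.protein_id, t + 1) in site_set and res != "K")
                    for t, res in targets
                )
                if ok:
                    for t, res in targets:
                        seq[t] = res
                    truth.motif_assignment[key] = midx
                else:
                    truth.motif_assignment[key] = -1
            else:
                truth.motif_assignment[key] = -1

    edited = [
        ProteinRecord(p.protein_id, "".join(sequences[p.protein_id]), p.description)
        for p in proteins
    ]
    return edited, sorted(sites), truth


def assign_effects(
    truth: GroundTruth,
    proteins: list[ProteinRecord],
    sites: list[tuple[str, int]],
    frac_protein_de: float = 0.1,
    protein_effect_log2: float = 1.0,
    frac_site_de: float = 0.1,
    site_effect_log2: float = 1.5,
    anticorrelated: bool = False,
    seed: int = 0,
) -> GroundTruth:
    """Plant log2 treatment effects on proteins and on Kcr sites.

    Differential proteins get ``±protein_effect_log2`` (sign random);
    differential sites get an *additional* ``±site_effect_log2`` on top of
    their protein's effect. With ``anticorrelated=True`` a differential
    site on a differential protein takes the opposite sign of the protein
    effect, mimicking discordant protein/PTM regulation.
    """
    rng = np.random.default_rng(seed)
    for prot in proteins:
        eff = 0.0
        if rng.random() < frac_protein_de:
            eff = protein_effect_log2 * (1 if rng.random() < 0.5 else -1)
        truth.protein_effects[prot.protein_id] = eff
    for key in sites:
        eff = 0.0
        if rng.random() < frac_site_de:
            peff = truth.protein_effects.get(key[0], 0.0)
            if anticorrelated and peff != 0.0:
                eff = -np.sign(peff) * site_effect_log2
            else:
                eff = site_effect_log2 * (1 if rng.random() < 0.5 else -1)
        truth.site_effects[key] = eff
    return truth


# ---------------------------------------------------------------------------
# Reporter-intensity simulation
# ---------------------------------------------------------------------------

def _window(seq: str, pos1: int, flank: int = 10, pad: str = "_") -> str:
    i = pos1 - 1
    left = seq[max(0, i - flank): i]
    right = seq[i + 1: i + 1 + flank]
    return pad * (flank - len(left)) + left + seq[i] + right + pad * (flank - len(right))


def simulate_intensities(
    proteins: list[ProteinRecord],
    peptides: list[PeptideTemplate],
    sites: list[tuple[str, int]],
    truth: GroundTruth,
    design: ChannelDesign | None = None,
    base_log2_mean: float = 20.0,
    noise_sd: float = 0.25,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate 6-plex reporter intensities for peptides and Kcr sites.

    Log2 intensities are Gaussian around ``base_log2_mean`` plus a
    protein baseline, a peptide (or site) response offset, the planted
    treatment effect in T channels, and N(0, noise_sd) measurement noise —
    i.e. intensities are log-normal, the model under which a two-sample
    t-test on log2 values is exactly specified. Cells are deleted
    completely at random at ``missing_rate``. Site rows get a localization
    probability from a two-component Beta mixture with mass on either side
    of the conventional 0.75 filter.
    """
    design = design or ChannelDesign.default()
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    seqs = {p.protein_id: p.sequence for p in proteins}
    prot_base = {p.protein_id: rng.normal(0.0, 1.5) for p in proteins}
    channels = list(design.channel_labels)
    is_t = np.array([design.group_of[c] == "T" for c in channels])

    pep_rows = []
    for pep in peptides:
        offset = rng.normal(0.0, 1.0)
        eff = truth.protein_effects.get(pep.protein_id, 0.0)
        log2 = (
            base_log2_mean
            + prot_base[pep.protein_id]
            + offset
            + eff * is_t
            + rng.normal(0.0, noise_sd, size=len(channels))
        )
        vals = np.exp2(log2)
        if missing_rate > 0:
            vals = np.where(rng.random(len(channels)) < missing_rate, np.nan, vals)
        pep_rows.append(
            {"peptide_seq": pep.sequence, "protein_id": pep.protein_id,
             "is_unique": int(pep.is_unique), **dict(zip(channels, vals))}
        )
    pep_df = pd.DataFrame(
        pep_rows, columns=["peptide_seq", "protein_id", "is_unique", *channels]
    )

    site_rows = []
    for pid, pos1 in sites:
        offset = rng.normal(0.0, 1.0)
        eff = truth.protein_effects.get(pid, 0.0) + truth.site_effects.get(
            (pid, pos1), 0.0
        )
        log2 = (
            base_log2_mean
            + prot_base[pid]
            + offset
            + eff * is_t
            + rng.normal(0.0, noise_sd, size=len(channels))
        )
        vals = np.exp2(log2)
        if missing_rate > 0:
            vals = np.where(rng.random(len(channels)) < missing_rate, np.nan, vals)
        # mixture: mostly well-localized (Beta(40,2), mass > 0.9), a minority
        # ambiguous (Beta(4,4), mostly below 0.75)
        if rng.random() < 0.85:
            loc = rng.beta(40.0, 2.0)
        else:
            loc = rng.beta(4.0, 4.0)
        site_rows.append(
            {"protein_id": pid, "position": pos1,
             "window": _window(seqs[pid], pos1),
             "localization_prob": loc, **dict(zip(channels, vals))}
        )
    site_df = pd.DataFrame(
        site_rows,
        columns=["protein_id", "position", "window", "localization_prob", *channels],
    )
    return pep_df, site_df


# ---------------------------------------------------------------------------
# Ortholog simulation
# ---------------------------------------------------------------------------

def generate_orthologs(
    proteins: list[ProteinRecord],
    species_names: list[str],
    substitution_rate: float = 0.1,
    kcr_sites: list[tuple[str, int]] | None = None,
    kcr_keep: float = 0.8,
    control_keep: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, list[ProteinRecord]], GroundTruth]:
    """Evolve per-species ortholog proteomes with controlled K retention.

    Each ortholog is the source protein with residues substituted
    independently at ``substitution_rate`` — except lysines, which are
    retained with probability ``kcr_keep`` (crotonylated) or
    ``control_keep`` (all other K). Substitutions never introduce a lysine,
    so a K column in the ortholog exists iff the retention draw kept it and
    the recorded draws are exact conservation ground truth. Sequence length
    is preserved (no indels).
    """
    for name, rate in (
        ("substitution_rate", substitution_rate),
        ("kcr_keep", kcr_keep),
        ("control_keep", control_keep),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    kcr_set = set(kcr_sites or [])
    rng = np.random.default_rng(seed)
    non_k = [a for a in AMINO_ACIDS if a != "K"]
    truth = GroundTruth(
        conservation_rates={s: (kcr_keep, control_keep) for s in species_names}
    )
    orthologs: dict[str, list[ProteinRecord]] = {}
    for species in species_names:
        draws: dict[tuple[str, int], tuple[bool, bool]] = {}
        recs = []
        for prot in proteins:
            out = []
            for idx, res in enumerate(prot.sequence):
                if res == "K":
                    is_kcr = (prot.protein_id, idx + 1) in kcr_set
                    keep = rng.random() < (kcr_keep if is_kcr else control_keep)
                    draws[(prot.protein_id, idx + 1)] = (is_kcr, keep)
                    if keep:
                        out.append("K")
                    else:
                        out.append(non_k[int(rng.integers(len(non_k)))])
                elif rng.random() < substitution_rate:
                    choices = [a for a in non_k if a != res]
                    out.append(choices[int(rng.integers(len(choices)))])
                else:
                    out.append(res)
            recs.append(
                ProteinRecord(
                    f"{species}|{prot.protein_id}", "".join(out),
                    f"simulated ortholog of {prot.protein_id}",
                )
            )
        orthologs[species] = recs
        truth.retention[species] = draws
    return orthologs, truth
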