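"""Synthetic tRNA gene families and age-series small-RNA libraries.

The simulator produces the statistical structure the pipeline assumes, with
full ground truth, so every stage is testable without external downloads:

* multicopy homologous gene families — identical and near-identical copies,
  optional introns, optional pseudogenes;
* fragments concentrated at the mature 5' and 3' ends (tRNA halves, 30-35 nt,
  from cleavage at the anticodon loop), 3' fragments with or without the
  terminal CCA, plus middle fragments, with +-2 nt boundary jitter
  (discretized Gaussian, sigma 1 nt — ragged cleavage at single-stranded
  loops);
* planted base-modification signatures: A-to-G at the anticodon wobble
  position at configurable penetrance (default 0.97), a mixed-base
  misincorporation site in the T-loop (m1A signature), and optional planted
  genomic mutations;
* abundance coupled to genomic copy number and age:
  E[reads] = depth_per_copy x copy_number x (1 + s x day), Poisson counts
  (default s = 0.11, giving the roughly 2.3-fold rise over a 12-day course
  that aged nematode libraries show);
* a 3' sequencing adapter appended to every insert before truncation to the
  instrument read length, and a configurable fraction of random background
  reads.

Identical (config, seed) pairs yield byte-identical libraries and truth
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference_builder import TRNAGeneRecord

FRAG_TYPES = ("5p", "3p_cca", "3p_nocca", "middle")

# anticodons cycled over families; half start with A so wobble-editing
# signatures are always represented, and the first eleven amino acids are
# distinct so small simulations have amino-acid-pure family structure
DEFAULT_ANTICODONS = [
    ("Ala", "AGC"), ("Lys", "CTT"), ("Arg", "ACG"), ("Asp", "GTC"),
    ("Ile", "AAT"), ("Gln", "TTG"), ("Ser", "AGA"), ("Thr", "AGT"),
    ("Gly", "GCC"), ("Val", "AAC"), ("Pro", "TGG"), ("Ser", "CGA"),
]

ANTICODON_OFFSET = 33   # wobble base, mature coordinates
INTRON_AFTER = 38
M1A_FROM_END = 19       # T-loop site: mature position L - 19

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions emulated."""

    n_families: int = 10
    copies_per_family: Sequence[int] | None = None  # default: sampled 1-25
    anticodons: Sequence[tuple[str, str]] | None = None  # default: cycled list
    within_family_divergence: float = 0.0           # per-base substitution prob
    intron_prob: float = 0.2
    intron_length: tuple[int, int] = (11, 20)
    pseudogene_prob: float = 0.0
    mature_length: tuple[int, int] = (70, 90)       # before CCA
    editing_rate_a34: float = 0.97
    m1a_site: bool = True
    m1a_spectrum: tuple[float, float, float, float] = (0.4, 0.25, 0.2, 0.15)  # A,C,G,T
    planted_mutations: Sequence[tuple[int, int, str]] = ()  # (family, mature pos, alt)
    frag_types: Sequence[str] | None = None         # per family; default cycles
    frag_length_5p: int = 35
    frag_length_3p: int = 33
    frag_length_middle: int = 30
    boundary_jitter_sd: float = 1.0
    age_points: Sequence[float] = (0, 5, 8, 12)
    age_slope: float = 0.11                         # s in 1 + s*day
    depth_per_copy: float = 30.0                    # expected reads/copy at day 0
    background_rate: float = 0.02
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    read_cap: int = 35                              # max insert size kept
    read_length: int = 50                           # instrument read length

    def __post_init__(self) -> None:
        for name in ("within_family_divergence", "pseudogene_prob", "intron_prob",
                     "editing_rate_a34", "background_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.read_cap < 15:
            raise ValueError("read_cap must be >= 15")


@dataclass
class TruthTable:
    """Ground truth: one row per non-background read, one per family."""

    per_read: pd.DataFrame    # read_id, family, gene_id, frag start/end, edits
    per_family: pd.DataFrame  # family, frag_type, interval, expected per age


@dataclass
class FastqRecord:
    read_id: str
    sequence: str

    def format(self) -> str:
        return f"@{self.read_id}\n{self.sequence}\n+\n{'I' * len(self.sequence)}\n"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _mutate_each_base(rng: np.random.Generator, seq: str, p: float,
                      protect: range) -> str:
    arr = list(seq)
    for i in range(len(arr)):
        if i in protect:
            continue
        if rng.random() < p:
            arr[i] = [b for b in "ACGT" if b != arr[i]][rng.integers(0, 3)]
    return "".join(arr)


def simulate_gene_set(
    config: SimulationConfig, seed: int
) -> tuple[list[TRNAGeneRecord], dict[str, str]]:
    """Simulate homologous tRNA gene families and the genome carrying them.

    Family f's copy 0 carries the family consensus exactly; further copies
    diverge per-base at ``within_family_divergence``.  The wobble position is
    forced to the anticodon's first base and, when ``m1a_site`` is on, an A is
    planted at the T-loop site so modification signatures have a substrate.
    Gene ids are ``fam<f>_copy<c>``.
    """
    rng = np.random.default_rng(seed)
    if config.copies_per_family is not None:
        copies = list(config.copies_per_family)
        if len(copies) != config.n_families:
            raise ValueError("copies_per_family length must equal n_families")
    else:
        copies = [int(c) for c in rng.integers(1, 26, size=config.n_families)]

    anticodon_cycle = list(config.anticodons) if config.anticodons else DEFAULT_ANTICODONS
    records: list[TRNAGeneRecord] = []
    genome_parts: list[str] = [_random_seq(rng, 40)]
    pos = 40
    for fam in range(config.n_families):
        aa, anticodon = anticodon_cycle[fam % len(anticodon_cycle)]
        L = int(rng.integers(*config.mature_length))
        consensus = list(_random_seq(rng, L))
        consensus[ANTICODON_OFFSET:ANTICODON_OFFSET + 3] = anticodon
        if config.m1a_site:
            # mature coordinates include the 3'-CCA: position (L+3) - 19
            consensus[L + 3 - M1A_FROM_END] = "A"
        protect = range(ANTICODON_OFFSET, ANTICODON_OFFSET + 3)
        consensus = "".join(consensus)
        has_intron = rng.random() < config.intron_prob
        for c in range(copies[fam]):
            spliced = consensus if c == 0 else _mutate_each_base(
                rng, consensus, config.within_family_divergence, protect)
            if has_intron:
                ilen = int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
                gene_seq = spliced[:INTRON_AFTER] + _random_seq(rng, ilen) + spliced[INTRON_AFTER:]
                introns = [(INTRON_AFTER, INTRON_AFTER + ilen)]
            else:
                gene_seq, introns = spliced, []
            strand = "+" if rng.random() < 0.5 else "-"
            start = pos
            end = start + len(gene_seq)
            genomic = gene_seq if strand == "+" else _revcomp(gene_seq)
            flank = _random_seq(rng, int(rng.integers(25, 50)))
            genome_parts.extend([genomic, flank])
            pos = end + len(flank)
            records.append(TRNAGeneRecord(
                gene_id=f"fam{fam}_copy{c}",
                chrom="sim",
                start=start,
                end=end,
                strand=strand,
                amino_acid=aa,
                anticodon=anticodon,
                anticodon_start=ANTICODON_OFFSET,
                introns=introns,
                is_pseudogene=bool(rng.random() < config.pseudogene_prob),
                gene_seq=gene_seq,
            ))
    return records, {"sim": "".join(genome_parts)}


def _family_mature(records: Sequence[TRNAGeneRecord], fam: int) -> tuple[str, str]:
    """(gene_id of copy 0, mature sequence) for one family."""
    from .reference_builder import build_mature_sequence

    gene = next(g for g in records if g.gene_id == f"fam{fam}_copy0")
    return gene.gene_id, build_mature_sequence(gene)


def _fragment_interval(
    rng: np.random.Generator, frag_type: str, L: int, config: SimulationConfig
) -> tuple[int, int]:
    jitter = lambda: int(round(rng.normal(0, config.boundary_jitter_sd)))
    if frag_type == "5p":
        length = config.frag_length_5p + jitter()
        start, end = 0, min(L, max(15, min(length, config.read_cap)))
    elif frag_type == "3p_cca":
        length = config.frag_length_3p + jitter()
        end = L
        start = max(0, end - max(15, min(length, config.read_cap)))
    elif frag_type == "3p_nocca":
        length = config.frag_length_3p + jitter()
        end = L - 3
        start = max(0, end - max(15, min(length, config.read_cap)))
    elif frag_type == "middle":
        length = max(15, min(config.frag_length_middle + jitter(), config.read_cap))
        center = L // 2 + jitter()
        start = max(0, center - length // 2)
        end = min(L, start + length)
    else:
        raise ValueError(f"unknown fragment type {frag_type!r}")
    return start, end


def nominal_interval(frag_type: str, L: int, config: SimulationConfig) -> tuple[int, int]:
    """Jitter-free fragment interval, the per-family truth interval."""
    if frag_type == "5p":
        return 0, min(L, min(config.frag_length_5p, config.read_cap))
    if frag_type == "3p_cca":
        return max(0, L - min(config.frag_length_3p, config.read_cap)), L
    if frag_type == "3p_nocca":
        return max(0, L - 3 - min(config.frag_length_3p, config.read_cap)), L - 3
    length = min(config.frag_length_middle, config.read_cap)
    start = max(0, L // 2 - length // 2)
    return start, min(L, start + length)


def expected_count(config: SimulationConfig, copy_number: int, day: float) -> float:
    """Age-amplitude model: E[reads] = depth_per_copy x copies x (1 + s x day)."""
    return config.depth_per_copy * copy_number * (1 + config.age_slope * day)


def simulate_reads(
    config: SimulationConfig,
    gene_set: Sequence[TRNAGeneRecord],
    age_index: int,
    seed: int,
) -> tuple[list[FastqRecord], TruthTable]:
    """One age library: sense fragments of family-consensus mature tRNAs.

    Fragment counts are Poisson around the age-amplitude model; each read
    carries the planted edits it covers, then the 3' adapter, and is
    truncated to the instrument read length.  Background reads are uniform
    random sequence.  Deterministic given (config, seed, age_index).
    """
    day = float(config.age_points[age_index])
    rng = np.random.default_rng(np.random.SeedSequence([seed, age_index]))
    spectrum = np.asarray(config.m1a_spectrum, dtype=float)
    spectrum = spectrum / spectrum.sum()
    mutations = {(fam, pos): alt for fam, pos, alt in config.planted_mutations}

    frag_types = list(config.frag_types) if config.frag_types else [
        FRAG_TYPES[i % len(FRAG_TYPES)] for i in range(config.n_families)
    ]

    copy_count: dict[int, int] = {}
    for g in gene_set:
        fam = int(g.gene_id.split("_")[0][3:])
        copy_count[fam] = copy_count.get(fam, 0) + 1

    reads: list[FastqRecord] = []
    truth_rows: list[dict] = []
    family_rows: list[dict] = []
    serial = 0
    for fam in sorted(copy_count):
        gene_id, mature = _family_mature(gene_set, fam)
        L = len(mature)
        frag_type = frag_types[fam]
        mu = expected_count(config, copy_count[fam], day)
        n = int(rng.poisson(mu))
        nom = nominal_interval(frag_type, L, config)
        family_rows.append({
            "family": fam, "gene_id": gene_id, "frag_type": frag_type,
            "copy_number": copy_count[fam], "truth_start": nom[0],
            "truth_end": nom[1], "expected_count": mu, "day": day,
        })
        for _ in range(n):
            start, end = _fragment_interval(rng, frag_type, L, config)
            frag = list(mature[start:end])
            edits = []
            ac = ANTICODON_OFFSET
            if start <= ac < end and mature[ac] == "A" and rng.random() < config.editing_rate_a34:
                frag[ac - start] = "G"
                edits.append(f"A34G@{ac}")
            if config.m1a_site:
                m1a_pos = L - M1A_FROM_END
                if start <= m1a_pos < end and mature[m1a_pos] == "A":
                    base = str(BASES[rng.choice(4, p=spectrum)])
                    if base != frag[m1a_pos - start]:
                        edits.append(f"m1A@{m1a_pos}:{base}")
                    frag[m1a_pos - start] = base
            for (mfam, pos), alt in mutations.items():
                if mfam == fam and start <= pos < end:
                    frag[pos - start] = alt
                    edits.append(f"mut@{pos}:{alt}")
            insert = "".join(frag)
            read_id = f"d{day:g}_r{serial:07d}"
            serial += 1
            seq = (insert + config.adapter)[:config.read_length]
            reads.append(FastqRecord(read_id, seq))
            truth_rows.append({
                "read_id": read_id, "family": fam, "gene_id": gene_id,
                "start": start, "end": end, "edits": ";".join(edits) or ".",
            })

    n_background = int(rng.poisson(config.background_rate * max(serial, 1)))
    for _ in range(n_background):
        length = int(rng.integers(15, config.read_cap + 1))
        seq = (_random_seq(rng, length) + config.adapter)[:config.read_length]
        reads.append(FastqRecord(f"d{day:g}_bg{serial:07d}", seq))
        serial += 1

    truth = TruthTable(
        per_read=pd.DataFrame(
            truth_rows,
            columns=["read_id", "family", "gene_id", "start", "end", "edits"]),
        per_family=pd.DataFrame(family_rows),
    )
    return reads, truth


def write_fastq(reads: Sequence[FastqRecord], path: str | Path) -> None:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(r.format())


# --- flat key=value config file --------------------------------------------

def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write the config as flat ``key = value`` lines (lists comma-joined)."""
    with open(path, "w") as fh:
        for key, value in asdict(config).items():
            if isinstance(value, (list, tuple)):
                value = ",".join(
                    ":".join(str(x) for x in v) if isinstance(v, (list, tuple)) else str(v)
                    for v in value
                )
            fh.write(f"{key} = {value}\n")


def load_config(path: str | Path) -> SimulationConfig:
    defaults = SimulationConfig()
    kwargs: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            default = getattr(defaults, key)
            kwargs[key] = _parse_value(raw, default)
    return SimulationConfig(**kwargs)


def _parse_value(raw: str, default):
    if isinstance(default, bool):
        return raw in {"True", "true", "1"}
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    if isinstance(default, (list, tuple)) or default is None:
        if raw in {"", "None"}:
            return None if default is None else ()
        items = [x for x in raw.split(",") if x]
        out = []
        for item in items:
            if ":" in item:
                parts = item.split(":")
                out.append(tuple(_scalar(p) for p in parts))
            else:
                out.append(_scalar(item))
        return tuple(out)
    return raw


def _scalar(x: str):
    try:
        return int(x)
    except ValueError:
        try:
            return float(x)
        except ValueError:
            return x


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
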