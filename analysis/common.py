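"""Shared paths and loaders for the numbered analysis scripts."""

from __future__ import annotations

import os

from pprdup import io as pio

DATA_DIR = os.path.join("results", "data")
OUT_DIR = "results"

GENOME_FILES = {
    "A": "sativa_like",
    "B": "rufipogon_like",
    "O": "outgroup",
}


def genome_paths(label: str, data_dir: str = DATA_DIR) -> dict[str, str]:
    name = GENOME_FILES[label]
    return {
        "fasta": os.path.join(data_dir, f"{name}.fa"),
        "gff3": os.path.join(data_dir, f"{name}.gff3"),
        "proteins": os.path.join(data_dir, f"{name}.pep.fa"),
        "cds": os.path.join(data_dir, f"{name}.cds.fa"),
        "domains": os.path.join(data_dir, f"{name}.domains.tsv"),
        "repeats": os.path.join(data_dir, f"{name}.repeats.bed"),
        "counts": os.path.join(data_dir, f"{name}.counts.tsv"),
    }


def load_genome(label: str, data_dir: str = DATA_DIR):
    p = genome_paths(label, data_dir)
    return pio.load_genome(
        GENOME_FILES[label], p["fasta"], p["gff3"], p["proteins"], p["cds"]
    )


def load_hits(label: str, data_dir: str = DATA_DIR):
    return pio.read_domain_hits(genome_paths(label, data_dir)["domains"])


def load_repeats(label: str, data_dir: str = DATA_DIR):
    return pio.read_bed(genome_paths(label, data_dir)["repeats"])


def out_path(name: str) -> str:
    os.makedirs(OUT_DIR, exist_ok=True)
    return os.path.join(OUT_DIR, name)
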