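"""Synthetic five-muscle proteomes with planted phenotype-associated proteins.

The default layout emulates the study design behind the fiber-type screen:
five muscle samples — wild-type flight, jump, and leg muscle, salm-knockdown
flight muscle, and salm-overexpression leg muscle — spanning combinations of
contractile type (fibrillar/tubular), mitochondrial network type
(parallel/grid), and salm expression, with replicate TMT-like channels and
multiplicative log-normal noise.

Phenotypes are modeled with graded per-muscle strengths rather than pure
0/1 labels: leg muscle is a mixture of parallel (Fiber I) and grid-like
(Fibers II/III) regions, RNAi knockdown leaves residual salm expression and
an incomplete molecular conversion, and jump muscle expresses intermediate
salm. A protein planted for phenotype p with fold change f and sign +
receives multiplier f**strength_p(muscle) in each muscle (sign -:
f**-strength). This grading is what makes the ten phenotype/sign classes
mutually distinguishable by a ratio-threshold screen: with pure 0/1
strengths, complementary classes (e.g. Fibrillar- vs Tubular+) would have
identical fold changes in every comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..screen import AbundanceMatrix, PhenotypeTable

__all__ = [
    "MuscleType",
    "ProteomeSimParams",
    "PHENOTYPES",
    "default_muscle_types",
    "make_proteome",
    "write_proteome",
]

PHENOTYPES = ("fibrillar", "tubular", "parallel", "grid", "salm")


@dataclass
class MuscleType:
    """One muscle sample group with categorical attributes and graded strengths."""

    label: str
    contractile: str                    # {fibrillar | tubular}
    network: str                        # {parallel | grid}
    salm: str                           # {high | low | none}
    strengths: dict = field(default_factory=dict)   # phenotype -> [0, 1]


def default_muscle_types() -> list[MuscleType]:
    """The five-muscle design with graded phenotype strengths.

    Strengths encode molecular dose: wild-type leg is ~1/3 parallel Fiber I
    vs ~2/3 grid Fibers II/III; salm KD flight retains residual salm
    (incomplete RNAi) and partial tubular conversion; salm OE leg keeps a
    leg-like mixed network while its contractile network turns fibrillar.
    """
    return [
        MuscleType("flight_wt", "fibrillar", "parallel", "high",
                   {"fibrillar": 1.0, "tubular": 0.0, "parallel": 1.0,
                    "grid": 0.0, "salm": 1.0}),
        MuscleType("jump_wt", "tubular", "parallel", "low",
                   {"fibrillar": 0.0, "tubular": 1.0, "parallel": 1.0,
                    "grid": 0.0, "salm": 0.75}),
        MuscleType("leg_wt", "tubular", "grid", "none",
                   {"fibrillar": 0.0, "tubular": 1.0, "parallel": 0.25,
                    "grid": 0.85, "salm": 0.0}),
        MuscleType("flight_salm_kd", "tubular", "grid", "low",
                   {"fibrillar": 0.0, "tubular": 0.4, "parallel": 0.0,
                    "grid": 1.0, "salm": 0.55}),
        MuscleType("leg_salm_oe", "fibrillar", "grid", "high",
                   {"fibrillar": 1.0, "tubular": 0.0, "parallel": 0.25,
                    "grid": 0.2, "salm": 1.0}),
    ]


@dataclass
class ProteomeSimParams:
    """Design and noise settings for one simulated abundance table.

    ``planted`` is a list of ``(phenotype, sign, n_proteins, fold_change)``
    tuples, e.g. ``("fibrillar", "+", 25, 4.0)``. Defaults: 2000 background
    proteins, two replicate channels per muscle, 10% multiplicative noise,
    baseline abundance 1e5 (TMT reporter-intensity scale).
    """

    n_proteins: int = 2000
    muscle_types: list[MuscleType] = field(default_factory=default_muscle_types)
    replicates_per_type: int = 2
    planted: list[tuple[str, str, int, float]] = field(default_factory=list)
    noise_cv: float = 0.1
    baseline_abundance: float = 1.0e5
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 0 or self.replicates_per_type < 1:
            raise ValueError("need n_proteins >= 0 and replicates_per_type >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.baseline_abundance <= 0:
            raise ValueError("baseline_abundance must be > 0")
        labels = [m.label for m in self.muscle_types]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate muscle labels")
        for pheno, sign, n, fc in self.planted:
            if pheno not in PHENOTYPES:
                raise ValueError(f"unknown phenotype: {pheno!r}")
            if sign not in {"+", "-"}:
                raise ValueError(f"sign must be '+' or '-', got {sign!r}")
            if n < 0:
                raise ValueError("planted count must be >= 0")
            if fc <= 1:
                raise ValueError("planted fold_change must be > 1")


def phenotype_table(muscle_types: list[MuscleType]) -> PhenotypeTable:
    return PhenotypeTable(
        {m.label: {"contractile": m.contractile, "network": m.network, "salm": m.salm}
         for m in muscle_types}
    )


def make_proteome(params: ProteomeSimParams) -> tuple[AbundanceMatrix, dict[str, list[str]]]:
    """Simulate an abundance matrix; returns it with the planted-truth lists.

    Truth maps ``"<phenotype><sign>"`` (e.g. ``"fibrillar+"``) to the planted
    protein ids. At ``noise_cv=0`` the realized fold change between a
    full-strength carrier and a non-carrier equals the requested fold change
    exactly, and identical seeds give bitwise-identical tables.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    sample_ids: list[str] = []
    sample_muscles: list[str] = []
    for m in params.muscle_types:
        for r in range(1, params.replicates_per_type + 1):
            sample_ids.append(f"{m.label}_r{r}")
            sample_muscles.append(m.label)

    protein_ids = [f"bg_{i:05d}" for i in range(params.n_proteins)]
    rows = [np.full(len(sample_ids), params.baseline_abundance)
            for _ in range(params.n_proteins)]

    truth: dict[str, list[str]] = {}
    for pheno, sign, n, fc in params.planted:
        key = f"{pheno}{sign}"
        ids = [f"{pheno}{'pos' if sign == '+' else 'neg'}_{i:03d}" for i in range(n)]
        if set(ids) & set(protein_ids):
            raise ValueError(f"duplicate planted ids for {key}")
        truth[key] = ids
        exponent = 1.0 if sign == "+" else -1.0
        mult = np.array(
            [fc ** (exponent * m.strengths.get(pheno, 0.0))
             for m in params.muscle_types
             for _ in range(params.replicates_per_type)]
        )
        for pid in ids:
            protein_ids.append(pid)
            rows.append(params.baseline_abundance * mult)

    values = np.vstack(rows) if rows else np.empty((0, len(sample_ids)))
    if params.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(params.noise_cv**2)))
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=values.shape)
        values = values * noise

    frame = pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                         columns=sample_ids)
    matrix = AbundanceMatrix(values=frame,
                             sample_muscle=dict(zip(sample_ids, sample_muscles)))
    return matrix, truth


def write_proteome(
    out_dir: str | Path,
    matrix: AbundanceMatrix,
    truth: dict[str, list[str]] | None = None,
    params: ProteomeSimParams | None = None,
) -> dict[str, Path]:
    """Write abundance + sample-metadata TSVs (and truth/params JSON sidecars)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": out / "abundance.tsv",
        "samples": out / "samples.tsv",
    }
    matrix.values.to_csv(paths["abundance"], sep="\t")
    pd.DataFrame(
        {"sample_id": list(matrix.sample_muscle),
         "muscle_type": list(matrix.sample_muscle.values())}
    ).to_csv(paths["samples"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=2))
    if params is not None:
        paths["params"] = out / "sim_params.json"
        payload = asdict(params)
        paths["params"].write_text(json.dumps(payload, indent=2, default=str))
    return paths
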