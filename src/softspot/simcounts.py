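"""Negative-binomial RNA-seq count simulator with paired fruit structure.

Emulates the three-group sampling design used downstream: featured regions
of predicted rapid-softening fruits (RS-F), non-featured regions of a
subset of the same fruits (RS-NF, paired with their RS-F partner), and
featured regions of predicted control fruits (C-F).

Structure planted in the counts:

* **Group effect, criteria (i)** — a set of up/down genes whose RS-F vs C-F
  log2 fold change is nonzero, expressed only in a *responder* subset of the
  RS fruits (default half), reproducing the heterogeneity in which only
  some predicted-positive fruits show the consistent signature.
* **Mislabeled control** — one C-F fruit (default) receives the full RS
  signature, emulating a false-negative prediction slipping into the
  control group.
* **Region effect, criteria (ii)** — a disjoint set of genes differing
  between the featured and non-featured region *within* each RS fruit.
* **Fruit random effect** — a per-fruit, per-gene log2-normal effect shared
  by both samples of a fruit; this shared component is exactly what a
  paired analysis cancels and an unpaired one cannot.

Counts are NB with per-gene gamma-distributed dispersion; the expected
count is library-size x a length-weighted relative-abundance simplex, so
RPKM-style normalisation is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountSimConfig", "CountMatrix", "SimTruth", "simulate_counts"]


@dataclass(frozen=True)
class CountSimConfig:
    n_genes: int = 2000
    length_log_mean: float = 7.3  # lognormal over bp; median ~1.5 kb
    length_log_sd: float = 0.6
    baseline_log2_sd: float = 2.0  # spread of relative expression
    dispersion_shape: float = 2.0  # gamma over NB dispersion alpha
    dispersion_scale: float = 0.1  # mean alpha = shape*scale = 0.2
    n_fruits_rs: int = 10
    n_paired: int = 4  # RS fruits that also yield an RS-NF sample
    n_fruits_c: int = 10
    frac_up: float = 0.05  # criteria (i) DEG fractions
    frac_down: float = 0.05
    effect_lfc: float = 2.0  # |log2FC| of criteria (i) effects
    responder_fraction: float = 0.5  # RS fruits expressing the (i) effect
    mislabeled_controls: int = 1
    frac_paired_up: float = 0.05  # criteria (ii) DEG fractions
    frac_paired_down: float = 0.05
    paired_effect_lfc: float = 2.0
    fruit_random_effect_sd: float = 0.5  # log2 units, shared within fruit
    libsize_range: tuple[float, float] = (5e6, 15e6)
    seed: int = 0

    def __post_init__(self):
        if self.n_paired > self.n_fruits_rs:
            raise ValueError("n_paired cannot exceed n_fruits_rs")
        if self.mislabeled_controls > self.n_fruits_c:
            raise ValueError("more mislabeled controls than control fruits")
        for f in (self.frac_up, self.frac_down, self.responder_fraction,
                  self.frac_paired_up, self.frac_paired_down):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.frac_up + self.frac_down + self.frac_paired_up + self.frac_paired_down > 1.0:
            raise ValueError("DEG fractions exceed the gene universe")


@dataclass
class CountMatrix:
    counts: pd.DataFrame  # genes x samples, nonnegative ints
    gene_lengths: pd.Series  # bp, indexed like counts
    sample_meta: pd.DataFrame  # sample_id, group, fruit_id, library_size


@dataclass
class SimTruth:
    degs_i_up: list[str] = field(default_factory=list)
    degs_i_down: list[str] = field(default_factory=list)
    degs_ii_up: list[str] = field(default_factory=list)
    degs_ii_down: list[str] = field(default_factory=list)
    responder_fruits: list[str] = field(default_factory=list)
    mislabeled_controls: list[str] = field(default_factory=list)


def simulate_counts(config: CountSimConfig) -> tuple[CountMatrix, SimTruth]:
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    genes = [f"g{i:05d}" for i in range(g)]

    lengths = rng.lognormal(config.length_log_mean, config.length_log_sd, g)
    lengths = np.maximum(lengths, 150.0).round()
    base_log2 = rng.normal(0.0, config.baseline_log2_sd, g)
    dispersion = rng.gamma(config.dispersion_shape, config.dispersion_scale, g)

    # gene assignment: disjoint truth sets, drawn from a shuffled universe
    order = rng.permutation(g)
    n_up = int(round(config.frac_up * g))
    n_dn = int(round(config.frac_down * g))
    n_pu = int(round(config.frac_paired_up * g))
    n_pd = int(round(config.frac_paired_down * g))
    cut = np.cumsum([n_up, n_dn, n_pu, n_pd])
    i_up, i_dn = order[: cut[0]], order[cut[0] : cut[1]]
    ii_up, ii_dn = order[cut[1] : cut[2]], order[cut[2] : cut[3]]

    lfc_i = np.zeros(g)
    if config.effect_lfc:
        lfc_i[i_up] = config.effect_lfc
        lfc_i[i_dn] = -config.effect_lfc
    lfc_ii = np.zeros(g)
    if config.paired_effect_lfc:
        lfc_ii[ii_up] = config.paired_effect_lfc
        lfc_ii[ii_dn] = -config.paired_effect_lfc

    rs_fruits = [f"RS{i:02d}" for i in range(config.n_fruits_rs)]
    c_fruits = [f"C{i:02d}" for i in range(config.n_fruits_c)]
    n_resp = int(round(config.responder_fraction * config.n_fruits_rs))
    responders = set(rng.choice(rs_fruits, size=n_resp, replace=False)) if n_resp else set()
    mislabeled = set(rng.choice(c_fruits, size=config.mislabeled_controls,
                                replace=False)) if config.mislabeled_controls else set()

    # sample table: RS-F for every RS fruit, RS-NF for the first n_paired,
    # C-F for every control fruit
    samples = []
    for f in rs_fruits:
        samples.append((f"{f}_F", "RS-F", f))
    for f in rs_fruits[: config.n_paired]:
        samples.append((f"{f}_NF", "RS-NF", f))
    for f in c_fruits:
        samples.append((f"{f}_F", "C-F", f))

    fruit_effects = {f: rng.normal(0.0, config.fruit_random_effect_sd, g)
                     for f in rs_fruits + c_fruits}

    counts = np.zeros((g, len(samples)), dtype=np.int64)
    libsizes = rng.uniform(*config.libsize_range, len(samples))
    for j, (sid, group, fruit) in enumerate(samples):
        log2_mu = base_log2 + fruit_effects[fruit]
        rs_like = (group in ("RS-F", "RS-NF") and fruit in responders) or fruit in mislabeled
        if rs_like:
            log2_mu = log2_mu + lfc_i
        if group == "RS-F":
            log2_mu = log2_mu + lfc_ii
        rel = np.exp2(log2_mu) * lengths  # length-weighted abundance
        p = rel / rel.sum()
        mu = libsizes[j] * p
        r = 1.0 / np.maximum(dispersion, 1e-8)
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes,
                            columns=[s for s, _, _ in samples]),
        gene_lengths=pd.Series(lengths, index=genes, name="length_bp"),
        sample_meta=pd.DataFrame(
            [dict(sample_id=sid, group=grp, fruit_id=fr,
                  library_size=int(counts[:, j].sum()))
             for j, (sid, grp, fr) in enumerate(samples)]),
    )
    ga = np.asarray(genes)
    truth = SimTruth(
        degs_i_up=sorted(ga[i_up]), degs_i_down=sorted(ga[i_dn]),
        degs_ii_up=sorted(ga[ii_up]), degs_ii_down=sorted(ga[ii_dn]),
        responder_fruits=sorted(responders),
        mislabeled_controls=sorted(mislabeled),
    )
    return cm, truth
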