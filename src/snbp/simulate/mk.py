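"""Synthetic MK count tables with a known true alpha.

Per gene: Ds ~ Poisson(mean_ds), Ps ~ Poisson(mean_ps),
Dn ~ Poisson(mean_ds * r / (1 - alpha)), neutral Pn ~ Poisson(mean_ps * r)
where r is the neutral nonsynonymous/synonymous ratio, so the pooled
estimator alpha = 1 - (Ds*Pn)/(Dn*Ps) is centred on alpha_true.

A slightly-deleterious class of extra nonsynonymous polymorphisms can be
planted at low derived-allele frequency (< rare_freq_max): these bias the
naive estimator downward and are what the rare-SNP filter removes. Neutral
polymorphism frequencies are drawn above rare_freq_max so that with
rare_fraction = 0 the filter is a no-op. These distributional choices are
testing stand-ins, not a population-genetic model.
"""

from __future__ import annotations

from snbp.errors import ConfigError
from snbp.io.tables import PolymorphismRecord
from snbp.simulate.config import MKParams
from snbp.simulate.rng import substream


def simulate_mk_counts(
    params: MKParams, seed: int
) -> list[PolymorphismRecord]:
    """Generate per-site polymorphism/divergence records for n_genes genes."""
    params.validate()
    if params.alpha_true >= 1:
        raise ConfigError("alpha_true must be < 1")
    rng = substream(seed, "mk")
    r = params.neutral_ratio
    lam_dn = params.mean_ds * r / (1.0 - params.alpha_true)
    lam_pn = params.mean_ps * r
    f = params.rare_fraction
    lam_pn_rare = lam_pn * f / (1.0 - f) if f > 0 else 0.0

    records: list[PolymorphismRecord] = []
    for g in range(params.n_genes):
        gene = f"gene{g:04d}"
        ds = int(rng.poisson(params.mean_ds))
        dn = int(rng.poisson(lam_dn))
        ps = int(rng.poisson(params.mean_ps))
        pn = int(rng.poisson(lam_pn))
        pn_rare = int(rng.poisson(lam_pn_rare)) if lam_pn_rare > 0 else 0
        site = 0
        for _ in range(dn):
            records.append(
                PolymorphismRecord(gene, site, "nonsynonymous", "divergence")
            )
            site += 1
        for _ in range(ds):
            records.append(PolymorphismRecord(gene, site, "synonymous", "divergence"))
            site += 1
        for _ in range(pn):
            freq = float(rng.uniform(params.rare_freq_max, 1.0))
            records.append(
                PolymorphismRecord(
                    gene, site, "nonsynonymous", "polymorphism", frequency=freq
                )
            )
            site += 1
        for _ in range(ps):
            freq = float(rng.uniform(params.rare_freq_max, 1.0))
            records.append(
                PolymorphismRecord(
                    gene, site, "synonymous", "polymorphism", frequency=freq
                )
            )
            site += 1
        for _ in range(pn_rare):
            freq = float(rng.uniform(1e-3, params.rare_freq_max))
            records.append(
                PolymorphismRecord(
                    gene, site, "nonsynonymous", "polymorphism", frequency=freq
                )
            )
            site += 1
    return records
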