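# phytosynergy

Analysis tools for multi-herb formulation studies: Box–Behnken
response-surface optimization of extraction responses, median-effect
dose–response fitting, FPI and Chou–Talalay combination-index synergy
quantification for constant-ratio mixtures, and selectivity-index
safety scoring.

The package was built around a study of a Thai three-herb recipe —
*Garcinia mangostana* (GM), *Curcuma comosa* (CC) and *Acanthus
ebracteatus* (AE), blended at a fixed total mass of 30 g — and ships
that study's data tables as integrity-checked fixtures, but every
stage accepts user CSVs in the same layouts. It is aimed at natural-
products and formulation researchers who need the standard
extraction-optimization and drug-combination arithmetic as tested,
scriptable code rather than spreadsheet formulas.

## Models

**Response surface.** Extraction responses are fitted by OLS to the
full quadratic in herb masses (grams),

y = b₀ + Σᵢ bᵢxᵢ + Σᵢ bᵢᵢxᵢ² + Σᵢ<ⱼ bᵢⱼxᵢxⱼ + ε,

on the 15-run three-level Box–Behnken design (5 residual df, so the
Pareto significance line for standardized effects |b|/SE is
t(0.975, 5) = 2.571).

**Median-effect dose–response.** fa/(1−fa) = (D/Dm)ᵐ, fitted as a
straight line on log₁₀(fa/(1−fa)) vs log₁₀ D; Dm is the IC50 and any
ICxx follows as Dm·(x/(100−x))^(1/m).

**Synergy.** FPI = combination % inhibition / Σ single-herb %
inhibitions (≥ 2 synergism, [0.5, 2) additivity, < 0.5 antagonism), and
the constant-ratio combination index
CI(fa) = Σᵢ wᵢ·Dx_mix(fa)/Dxᵢ(fa) (< 1 synergism, = 1 additive, > 1
antagonism) with the dose-reduction index DRIᵢ satisfying
CI = Σ 1/DRIᵢ.

**Safety.** SI = IC20(cytotoxicity, L929 fibroblasts) /
IC50(anti-inflammatory, RAW 264.7 macrophages); SI > 1 is favorable.

See `docs/methods.md` for assumptions, numerical choices and
limitations.

## Worked example

```python
from phytosynergy import (
    ResponseSurfaceModel, load_response_table, selectivity_index,
)
from phytosynergy.synergy import fpi

# fit the ethanol-yield response surface on the bundled design table
table = load_response_table("ethanol", "yield")
res = ResponseSurfaceModel.from_response_table(table).fit()
print(res.summary())
```

```
Full-quadratic response surface: yield
n runs = 15, residual df = 5
R^2 = 97.37%   adj R^2 = 92.63%

term              coef          se         t
Intercept      10.3817      2.4351      4.26
GM             -0.4318      0.2484     -1.74
CC             -0.7333      0.2484     -2.95
AE             -0.4448      0.2484     -1.79
GM^2            0.0564      0.0102      5.55
CC^2            0.0730      0.0102      7.18
AE^2            0.0468      0.0102      4.60
GM*CC          -0.0325      0.0098     -3.33
GM*AE          -0.0157      0.0098     -1.61
CC*AE          -0.0223      0.0098     -2.28
```

The model explains 97.37% of the yield variance; the coefficients are
in actual gram units, so yield at any blend is the polynomial
evaluated at its masses (`res.predict((10, 10, 10))` → 4.857, the mean
of the three center replicates). `res.standardized_effects()` ranks
the coded-unit effects for a Pareto chart — here CC² (7.18) leads and
the 2.571 line separates the seven significant terms.

```python
# FPI of the best antioxidant blend vs the three single herbs (DPPH, 250 ug/mL)
print(fpi(80.33, (69.68, 74.35, 30.74)).rounded_1dp)   # 0.5

# selectivity index of the 5:10:15 blend
print(selectivity_index(35.93, 12.05).si_2dp)          # 2.98
```

An FPI of 0.5 sits exactly at the additivity boundary — the blend
inhibits half as much as its components' summed activities — and an SI
of 2.98 means anti-inflammatory doses are ~3× below the cytotoxic
threshold.

The same operations are available from the shell, e.g.:

```sh
phytosynergy rsm fit src/phytosynergy/data/table1_bbd_extraction.csv --response yield
phytosynergy synergy fpi --combo 80.33 --singles 69.68 74.35 30.74
phytosynergy safety si --ic20 35.93 --ic50 12.05
phytosynergy reproduce          # re-run every stage on the bundled tables
```

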