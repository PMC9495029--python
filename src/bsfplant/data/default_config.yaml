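# Default study setup for the larvae fatty-acid plant simulation.
# Every value here is overridable from a user config file (deep merge).

scenario: kitchen_waste
batch_mass: 10000.0        # kg larvae per batch

# Proximate composition per feed scenario: [mean, sd].
# dry_matter is % of wet mass; the rest are % of dry matter.
scenarios:
  chicken_manure:
    dry_matter: [80.7, 1.2]
    ash: [9.3, 1.8]
    organic_matter: [59.8, 0.4]
    crude_protein: [41.1, 0.3]
    ndf: [21.9, 0.6]
    adf: [12.6, 0.3]
    ether_extract: [30.1, 0.4]
  kitchen_waste:
    dry_matter: [87.7, 1.0]
    ash: [9.6, 1.6]
    organic_matter: [90.4, 1.6]
    crude_protein: [33.0, 1.0]
    ndf: [20.4, 0.6]
    adf: [13.2, 0.1]
    ether_extract: [34.3, 0.4]
  spent_grain:
    dry_matter: [83.1, 1.6]
    ash: [11.6, 0.5]
    organic_matter: [88.4, 0.5]
    crude_protein: [41.3, 0.5]
    ndf: [28.6, 1.0]
    adf: [15.0, 0.8]
    ether_extract: [31.0, 0.4]
  control:
    dry_matter: [32.7, 5.0]
    ash: [15.9, 3.1]
    organic_matter: [84.0, 1.4]
    crude_protein: [44.7, 3.4]
    ndf: [10.6, 4.2]
    adf: [19.0, 2.2]
    ether_extract: [9.7, 3.3]

# Mass split of crude fat over the four product fatty acids (lauric-dominant
# default; measured profiles are substrate-dependent and configurable).
fatty_acid_profile:
  lauric: 0.50
  myristic: 0.20
  palmitic: 0.20
  stearic: 0.10

flowsheet:
  enzyme: 100.0              # kg alcalase per batch
  conversion: 0.9            # protein hydrolysis extent
  wash_water: 20000.0        # kg per batch
  dilution_water: 15000.0    # kg per batch (with the enzyme into the reactor)
  backwash_water: 1058.0316191799856  # kg per batch (adsorber backwash)
  fat_carryover: 0.0         # fatty-acid leak into the protein cake
  water_to_light: 0.002      # moisture fraction reporting to the oil phase
  water_to_heavy: 0.08       # moisture fraction reporting to the protein cake

schedule:
  annual_operating_time: 7919.0   # h/yr (330 days)
  batch_time: 7.25                # h
  cycle_time: 2.75                # h between batch starts

economics:
  product_prices:            # currency per kg
    lauric_acid: 2.2
    myristic_acid: 2.4
    palmitic_acid: 1.8
    stearic_acid: 1.9
    protein_meal: 0.8
  waste_fee: 0.05            # currency per kg of waste stream
  steam_price: 30.0          # per MT
  cooling_water_price: 0.08  # per m3
  electricity_price: 0.12    # per kWh
  membrane_price: 150.0      # per m2 replaced
  enzyme_price: 6.0          # per kg alcalase
  capital_cost: 60000000.0
  tax_rate: 0.06             # flat tax on positive gross profit
  project_years: 20
  discount_rates: [0.07, 0.09, 0.11]
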