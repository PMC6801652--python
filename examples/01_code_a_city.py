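"""Code a city: load place records, deduplicate them, classify facilities.

Uses a synthetic city (the packaged generator) in place of exported
Google/OSM data; swap in `load_geojson`/`load_csv` for real files.
"""

import flcoder as flc

city = flc.generate_city(flc.CitySpec(seed=1))
print(f"raw place records (with cross-source duplicates): {len(city.places)}")

result = flc.code_facilities(city.places)
print(f"facilities after deduplication: {len(result.facilities)}")
print("category tally (share of all facilities):")
for cat, n in result.tally.items():
    if n:
        print(f"  {cat:>18}: {n:4d}  ({result.shares[cat]:.1%})")

# The four food categories make up the community food environment;
# non_food facilities are retained but excluded from food-environment
# analyses downstream.
n_food = sum(result.tally[c] for c in flc.FOOD_CATEGORIES)
print(f"food-environment facilities: {n_food}")
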