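"""Buffer-ring provider choice and a two-region disparity report.

Each region's own index radii define buffer disks around its providers; the
number of disks covering a participant is the number of providers they could
choose.  The table's two-level percentage convention reports the "no
provider" and ">= 1 provider" rows as shares of everyone, and the individual
m = 1, 2, ... rows as shares of the >= 1 subgroup.
"""

import json

from careshed import (
    bin_distances,
    build_choice_table,
    density_ratios,
    disparity_report,
    find_indices,
    generate_scenario,
    make_rural_shape,
    nearest_provider_distance,
    preset,
    provider_multiplicity,
)


def analyze_region(scenario):
    nearest = nearest_provider_distance(scenario.participants, scenario.providers)
    _, idx = find_indices(bin_distances(nearest), degree=4)
    tables = {}
    for key, est in (("pwd", idx.pwd), ("tld", idx.tld)):
        if est is None:
            tables[key] = None  # index undetected: table skipped, not borrowed
            continue
        mult = provider_multiplicity(scenario.participants, scenario.providers,
                                     est.buffer_radius)
        tables[key] = build_choice_table(mult, radius_m=est.buffer_radius)
    dens = density_ratios(len(scenario.participants), len(scenario.providers))
    return {"indices": idx, "tables": tables, "density": dens}


urban = analyze_region(generate_scenario(preset("urban-default"), seed=7))
rural = analyze_region(make_rural_shape(seed=7))

report = disparity_report({"urban": urban, "rural": rural})
for name, entry in report["regions"].items():
    print(f"--- {name}: PWD detected = {entry['pwd_detected']}, "
          f"{entry['density']['people_per_provider']} people/provider")
    for key, tab in entry["tables"].items():
        if tab.get("skipped"):
            print(f"  {key.upper()}: skipped ({tab['reason']})")
        else:
            print(f"  {key.upper()} (R = {tab['radius_m']:.0f} m): "
                  f"{tab['pct_without']}% without any provider, "
                  f"{tab['pct_with_any']}% with at least one")
print()
print("A higher share without any provider inside the buffer marks the")
print("less-served region; an undetected PWD marks an unprofitable one.")
print(json.dumps(report["regions"]["rural"]["tables"]["tld"], indent=1)[:400])
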