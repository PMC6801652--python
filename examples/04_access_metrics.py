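"""Access metrics: network distance, walking/cycling time, facility density."""

import flcoder as flc
from flcoder.access import RoadNetwork

# a toy road network in projected metres: two blocks and a diagonal
nodes = {"home": (0.0, 0.0), "corner": (300.0, 0.0), "school": (300.0, 400.0)}
net = RoadNetwork.from_edges(nodes, [("home", "corner", 300),
                                     ("corner", "school", 400),
                                     ("home", "school", 600)])

d = flc.route_distance_km(net, (0.0, 0.0), (300.0, 400.0))
print(f"network distance home -> school: {d:.2f} km "
      "(direct 600 m edge beats the 700 m corner route)")
print(f"  walking: {flc.travel_minutes(d, 'walk'):.1f} min at 5 km/h")
print(f"  cycling: {flc.travel_minutes(d, 'cycle'):.1f} min at 15 km/h")

# without a network: great-circle distance times the 1.3 detour factor
a, b = flc.GeoPoint(2.44, 41.54), flc.GeoPoint(2.45, 41.545)
print(f"no-network estimate: {flc.route_distance_km(None, a, b):.2f} km")

# density around a point of interest (e.g. a school inside the city)
city = flc.generate_city(flc.CitySpec(seed=1))
coded = flc.code_facilities(city.places)
centre = flc.GeoPoint(2.435, 41.530)
res = flc.facility_density(centre, radius_m=500.0, facilities=coded.food_facilities)
print(f"food facilities within 500 m of ({centre.lon:.4f}, {centre.lat:.4f}): {res.count}; "
      f"nearest at {res.nearest_km * 1000:.0f} m")
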