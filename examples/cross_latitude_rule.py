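"""The cross-latitude statistic of a least-cost sea route.

Extracts the shortest over-water route between a northern and a southern
region of the toy world and shows how its latitude extent collapses to the
cross-latitude distance: plain max - min within one hemisphere, but the
farthest |latitude| once the route crosses the equator (the en-route
temperature gradient reverses sign there).
"""

from searisk import build_transition, cross_latitude, extract_path, make_toy_world
from searisk.voyage import centroid_cell

world = make_toy_world()
graph = build_transition(world.grid)

origin, dest = world.regions[1], world.regions[3]  # west-high -> west-south
a = graph.node_of(*centroid_cell(origin, world.grid))
b = graph.node_of(*centroid_cell(dest, world.grid))
route = extract_path(graph, a, b)
lats = graph.node_lat[route]

print(f"route {origin.name} -> {dest.name}: {route.size} cells")
print(f"latitude extent: min {lats.min():.2f}, max {lats.max():.2f} degrees")
print(f"cross-latitude distance: {cross_latitude(lats.min(), lats.max()):.2f} degrees")
print()
print("The route crosses the equator, so the statistic is the absolute")
print("latitude farthest from the equator, not max - min (which would be")
print(f"{lats.max() - lats.min():.2f}).")
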