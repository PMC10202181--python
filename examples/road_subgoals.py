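"""Segment a road scene into CVT navigation sub-goals.

Renders a synthetic two-tone road with an obstacle, binarizes it by
2-means color clustering, extracts the road region anchored at the
bottom-center pixel, runs Lloyd's algorithm to place 11 centroidal
generators, and back-projects them through the camera geometry to robot-
and world-frame coordinates.
"""

from cvta import road, robot, simulate

cfg = simulate.RoadSceneConfig(
    obstacle_rects=[(60, 60, 30, 20)], color_noise_sd=8.0, seed=4
)
image, truth_mask = simulate.generate_road_scene(cfg)

camera = road.CameraGeometry(image_size=(cfg.width, cfg.height))
pose = robot.RobotState(x=1.0, y=0.5, heading=0.3)

mask = road.denoise(road.binarize_kmeans(image))
region = road.extract_road_region(mask)
result = road.cvt_lloyd(region, road.CvtConfig(n_generators=11, seed=1))
print(
    f"road region: {region.n_pixels} px; Lloyd converged in "
    f"{result.n_iterations} iterations "
    f"(J {result.j_history[0]:.3g} -> {result.j_history[-1]:.3g})"
)

goals = road.generate_subgoals(image, camera, pose, road.CvtConfig(11, seed=1))
print("  #   pixel (u, v)      robot (fwd, left) m   world (x, y) m")
for g in goals:
    print(
        f" {g.number:>2}   ({g.pixel[0]:6.1f}, {g.pixel[1]:6.1f})   "
        f"({g.robot[0]:5.2f}, {g.robot[1]:5.2f})        "
        f"({g.world[0]:5.2f}, {g.world[1]:5.2f})"
    )
# Sub-goal 1 is the farthest (top of image); each number maps to a numeric
# command of the selection interface. The objective J decreases every Lloyd
# iteration until the generators coincide with their cell centroids.
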