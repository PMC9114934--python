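# Longer-arm model: shoulder-to-elbow 0.41 m, elbow-to-wrist 0.32 m.
name: longer
shoulder_to_elbow_length: 0.41
elbow_to_wrist_length: 0.32
wrist_to_fingertip_length: 0.10
link_masses: [0.04, 0.024, 0.01]
joint_lower_limits: [-1.57, -0.85, -0.85, -1.50, -1.50, -0.50, -1.05]
joint_upper_limits: [0.70, 1.57, 0.85, 1.05, 1.57, 0.50, 1.05]
joint_axis_spec: ["shoulder_flexion:y", "shoulder_abduction:x", "shoulder_rotation:z", "elbow_flexion:y", "forearm_pronation:z", "wrist_flexion:y", "wrist_deviation:x"]
gravity: [0.0, 0.0, -9.81]
torque_limit: 1.0
integrator_substep: 0.002
joint_armature: 0.005
joint_damping: 0.05
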