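# Asymmetric anterior-posterior foot placement: the right (stepping) foot is
# placed 10 cm posteriorly.
name: asym_feet
seat_height: 0.44
foot_offset_r: -0.10
foot_offset_l: 0.0
max_time: 12.0
v_min: 0.8
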