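# Bench-study design: five MRI power-injector models and the 14 distinct
# injection protocols of the three protocol groups.  Line volumes and
# maximum injection power are illustrative placeholders (PS lines small,
# RP lines several-fold larger), not vendor data.  The two *_X entries are
# the experimental line-swap configurations: the lowest-power PS model
# fitted with the large RP tube line and vice versa.
days: 2

injectors:
  - injector_id: MedAcc
    pump_type: PS
    line_volume_ml: 6.0
    max_pressure: 12.0
    line_config: regular
  - injector_id: MedSol
    pump_type: PS
    line_volume_ml: 5.5
    max_pressure: 10.0
    line_config: regular
  - injector_id: CovOpt
    pump_type: PS
    line_volume_ml: 6.5
    max_pressure: 7.0
    line_config: regular
  - injector_id: UMax3
    pump_type: RP
    line_volume_ml: 60.0
    max_pressure: 6.0
    line_config: regular
  - injector_id: UMiss
    pump_type: RP
    line_volume_ml: 100.0
    max_pressure: 5.0
    line_config: regular
  - injector_id: CovOpt_X
    pump_type: PS
    line_volume_ml: 100.0
    max_pressure: 7.0
    line_config: experimental
  - injector_id: UMiss_X
    pump_type: RP
    line_volume_ml: 6.5
    max_pressure: 5.0
    line_config: experimental

protocols:
  # vVol: variable volume at a constant 5 ml/s flow rate
  - {protocol_id: vVol-15.0ml-5.0mls-gadoterate,  cm_type: gadoterate,  cm_volume_ml: 15.0, flow_rate_ml_s: 5.0, group: vVol}
  - {protocol_id: vVol-15.0ml-5.0mls-gadoteridol, cm_type: gadoteridol, cm_volume_ml: 15.0, flow_rate_ml_s: 5.0, group: vVol}
  - {protocol_id: vVol-10.0ml-5.0mls-gadoterate,  cm_type: gadoterate,  cm_volume_ml: 10.0, flow_rate_ml_s: 5.0, group: vVol}
  - {protocol_id: vVol-10.0ml-5.0mls-gadoteridol, cm_type: gadoteridol, cm_volume_ml: 10.0, flow_rate_ml_s: 5.0, group: vVol}
  - {protocol_id: vVol-5.0ml-5.0mls-gadoterate,   cm_type: gadoterate,  cm_volume_ml: 5.0,  flow_rate_ml_s: 5.0, group: vVol}
  - {protocol_id: vVol-5.0ml-5.0mls-gadoteridol,  cm_type: gadoteridol, cm_volume_ml: 5.0,  flow_rate_ml_s: 5.0, group: vVol}
  # cVol: constant 10 ml volume at variable flow (10 ml @ 5 ml/s overlaps
  # with the vVol grid and is listed once, under vVol)
  - {protocol_id: cVol-10.0ml-2.5mls-gadoterate,  cm_type: gadoterate,  cm_volume_ml: 10.0, flow_rate_ml_s: 2.5, group: cVol}
  - {protocol_id: cVol-10.0ml-2.5mls-gadoteridol, cm_type: gadoteridol, cm_volume_ml: 10.0, flow_rate_ml_s: 2.5, group: cVol}
  - {protocol_id: cVol-10.0ml-1.0mls-gadoterate,  cm_type: gadoterate,  cm_volume_ml: 10.0, flow_rate_ml_s: 1.0, group: cVol}
  - {protocol_id: cVol-10.0ml-1.0mls-gadoteridol, cm_type: gadoteridol, cm_volume_ml: 10.0, flow_rate_ml_s: 1.0, group: cVol}
  # mVol: micro volumes (2 ml)
  - {protocol_id: mVol-2.0ml-5.0mls-gadoterate,   cm_type: gadoterate,  cm_volume_ml: 2.0,  flow_rate_ml_s: 5.0, group: mVol}
  - {protocol_id: mVol-2.0ml-5.0mls-gadoteridol,  cm_type: gadoteridol, cm_volume_ml: 2.0,  flow_rate_ml_s: 5.0, group: mVol}
  - {protocol_id: mVol-2.0ml-1.0mls-gadoterate,   cm_type: gadoterate,  cm_volume_ml: 2.0,  flow_rate_ml_s: 1.0, group: mVol}
  - {protocol_id: mVol-2.0ml-1.0mls-gadoteridol,  cm_type: gadoteridol, cm_volume_ml: 2.0,  flow_rate_ml_s: 1.0, group: mVol}
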