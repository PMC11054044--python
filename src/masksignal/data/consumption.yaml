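# Default duty-cycle consumption budget of the mask monitor electronics.
# time_ratio is the fraction of each 1-second operating cycle the component
# draws current_ma; edit for other hardware.
battery_capacity_mah: 180
components:
  - component: "2x environmental sensor"
    time_ratio: 1.0
    current_ma: 1.8
  - component: "DC-DC converter"
    time_ratio: 1.0
    current_ma: 0.06
  - component: "MCU low-power mode"
    time_ratio: 0.9995
    current_ma: 2.1e-3
  - component: "MCU BLE 2dBm"
    time_ratio: 1.6e-4
    current_ma: 17.2
  - component: "MCU I2C transmittance"
    time_ratio: 3.36e-4
    current_ma: 1.0
  - component: "FET leakage"
    time_ratio: 1.0
    current_ma: 0.001
  - component: "MCU ADC measurement"
    time_ratio: 1.10e-8
    current_ma: 2.0
  - component: "Voltage divider + ADC measurement"
    time_ratio: 1.10e-8
    current_ma: 2.25
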