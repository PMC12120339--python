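tag_model,trigger_section,time_first_detection_to_trigger_h,time_of_day_triggered,mean_temp_pre_C,mean_temp_post_C,days_on_array
V7D-2x,Lake,45.07,07:44:54,,,25
V7D-2x,Estuary,18.12,06:16:58,,,14.18
V7D-2x,Lake,61.95,01:53:02,,,10.33
V7D-2x,Estuary,53.55,17:04:43,,,10.7
V7D-2x,Lake,12.33,23:19:59,,,45.26
V7DT-2x,Lake,16.13,02:43:43,12.26,36.52,32.28
V7DT-2x,Lake,16.52,02:57:55,12.26,36.33,25.94
V7DT-2x,Estuary,20.22,07:12:05,13.15,36.63,0.7
V7DT-2x,Lake,17.40,02:30:17,12.41,36.74,2
V7DT-2x,Lake,18.95,05:41:12,12.71,36.62,32.13
V7DT-2x,Lake,12.63,23:14:28,12.88,36.53,2.14
V7DT-2x,Lake,10.23,21:32:29,12.55,36.85,31.68
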