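TID,FID,Time,Longitude (°),Latitude (°),Elevation (m),Temperature (°C),Relative humidity (%),Atmospheric pressure (hpa),Oxygen concentration (%),FVC (%),Geomorphologic type,Vegetation type
18-068,QHL-001,2018/8/15 08:35,101.2273,36.6962,2659,16.21,73.3,742.8,20.35,/,Yellow River and Huangshui River valleys and basins small-region,"Annual ripening food crops and hardy cash crop field, deciduous fruit tree orchard"
18-069,QHL-002,2018/8/15 9:37,100.8533,36.9878,3209,14.54,75.1,701.7,20.28,/,Yellow River and Huangshui River valleys and basins small-region,Kobresia and forbs alpine meadow
18-070,QHL-003,2018/8/15 14:02,98.8713,37.1783,3831,17.41,54.9,643.1,20.30,92.20,South of Yellow River high mountains and basins small-region,Kobresia and forbs alpine meadow
18-071,QHL-004,2018/8/15 16:16,98.5498,37.0089,3118,20.58,46.7,703.7,20.43,/,South of Yellow River high mountains and basins small-region,"Annual ripening food crops and hardy cash crop field, deciduous fruit tree orchard"
18-072,QHL-005,2018/8/15 17:07,97.9563,37.0317,2936,16.41,51.9,718.0,20.36,/,Qaidam Basin small-region,Succulent saline dwarf subshrub desert
18-073,QHL-006,2018/8/15 18:17,97.3623,37.3730,2986,15.78,53.4,714.9,20.31,/,Qaidam Basin small-region,Subshrub and dwarf subshrub desert
18-074,QHL-007,2018/8/16 08:58,97.6494,36.9848,3061,13.27,70.8,709.7,20.38,/,Qaidam Basin small-region,Dwarf semi-arboreal desert
18-075,QHL-008,2018/8/16 10:04,98.0849,36.6686,3139,21.27,35.2,702.6,20.41,25.20,Qaidam Basin small-region,Subshrub and dwarf subshrub desert
18-076,QHL-009,2018/8/16 12:41,98.8741,36.7102,3229,18.37,42.0,696.1,20.52,/,Yellow River and Huangshui River valleys and basins small-region,Succulent saline dwarf subshrub desert
18-077,QHL-010,2018/8/16 14:54,99.6057,36.7544,3785,13.10,71.9,647.6,20.42,/,Yellow River and Huangshui River valleys and basins small-region,Kobresia and forbs alpine meadow
18-078,QHL-011,2018/8/16 16:30,99.8699,36.9810,3196,20.17,53.9,697.1,20.49,/,Yellow River and Huangshui River valleys and basins small-region,Temperate deciduous scrub
18-079,QHL-012,2018/8/16 17:02,99.9002,36.9787,3218,20.53,52.5,695.3,20.37,/,Yellow River and Huangshui River valleys and basins small-region,No vegetation
18-080,QHL-013,2018/8/17 17:00,101.7371,36.6396,2294,19.12,60.7,778.2,20.59,/,Yellow River and Huangshui River valleys and basins small-region,"Annual ripening food crops and hardy cash crop field, deciduous fruit tree orchard"
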