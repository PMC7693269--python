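site,latitude,event,mean_doy,se,n
NJ,39.2,fall_departure,192.3,2.8,23
NJ,39.2,winter_arrival,215.7,3.8,23
NJ,39.2,spring_departure,94.1,1.3,21
NJ,39.2,breeding_arrival,107.1,1.0,21
NJ,39.2,nest_initiation,127.4,0.9,20
MA_south,41.38,fall_departure,215.2,5.1,10
MA_south,41.38,winter_arrival,231.4,5.9,10
MA_south,41.38,spring_departure,107.4,2.6,6
MA_south,41.38,breeding_arrival,121.2,1.9,6
MA_south,41.38,nest_initiation,139.1,1.7,6
MA_north_ME,43.03,fall_departure,207.1,4.9,8
MA_north_ME,43.03,winter_arrival,223.7,6.2,8
MA_north_ME,43.03,spring_departure,109.9,2.3,7
MA_north_ME,43.03,breeding_arrival,127.0,1.7,7
MA_north_ME,43.03,nest_initiation,145.8,1.6,7
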