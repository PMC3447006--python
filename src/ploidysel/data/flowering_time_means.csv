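ploidy_group,line,role,generation,mean_days
diploid,D1,selected,0,44.2
diploid,D2,selected,0,44.2
diploid,DC,control,0,44.2
diploid,D1,selected,1,39.1
diploid,D2,selected,1,37.2
diploid,DC,control,1,40.5
diploid,D1,selected,2,43.8
diploid,D2,selected,2,44.6
diploid,DC,control,2,47.7
diploid,D1,selected,3,42.5
diploid,D2,selected,3,41.6
diploid,DC,control,3,45.3
diploid,D1,selected,4,34.3
diploid,D2,selected,4,32.7
diploid,DC,control,4,38.2
neotetraploid,N1,selected,0,47.1
neotetraploid,N2,selected,0,47.1
neotetraploid,NC,control,0,47.1
neotetraploid,N1,selected,1,41.0
neotetraploid,N2,selected,1,43.2
neotetraploid,NC,control,1,41.2
neotetraploid,N1,selected,2,48.3
neotetraploid,N2,selected,2,48.4
neotetraploid,NC,control,2,51.0
neotetraploid,N1,selected,3,44.4
neotetraploid,N2,selected,3,43.2
neotetraploid,NC,control,3,48.1
neotetraploid,N1,selected,4,35.3
neotetraploid,N2,selected,4,37.3
neotetraploid,NC,control,4,42.1
tetraploid,T1,selected,0,50.3
tetraploid,T2,selected,0,50.3
tetraploid,TC,control,0,50.3
tetraploid,T1,selected,1,42.9
tetraploid,T2,selected,1,44.0
tetraploid,TC,control,1,46.9
tetraploid,T1,selected,2,50.3
tetraploid,T2,selected,2,52.1
tetraploid,TC,control,2,55.7
tetraploid,T1,selected,3,47.0
tetraploid,T2,selected,3,48.5
tetraploid,TC,control,3,52.5
tetraploid,T1,selected,4,38.4
tetraploid,T2,selected,4,40.2
tetraploid,TC,control,4,44.2
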