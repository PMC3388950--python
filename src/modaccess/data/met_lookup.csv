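facility_type,met,source_note
ballistics hall,2.5,target shooting; typical pistol shooting value
croquet lawn,2.5,croquet
indoor small bore rifle range,2.5,target shooting
pistol shooting range,2.5,pistol shooting
archery range,2.5,recreational archery at standing rest
snooker hall,2.5,billiards/snooker
darts venue,2.5,darts
bowling green,3.0,lawn bowling
petanque terrain,3.0,boules
driving range,3.0,golf practice
yoga studio,3.0,hatha yoga
sailing club,3.0,recreational sailing
pilates studio,3.5,mat work
putting green,3.5,golf putting
curling rink,4.0,curling
table tennis hall,4.0,table tennis
horse riding school,4.0,general horseback riding
badminton court,4.5,social badminton
golf course,4.5,all golfing activities below 5 METs
pitch and putt course,4.3,short golf
cricket square,5.0,cricket batting and bowling
tennis court,5.0,doubles tennis
skate park,5.0,skateboarding
fitness suite,5.5,mixed gym circuit
basketball court,6.5,recreational game
netball court,6.5,recreational game
swimming pool,7.0,lap swimming within normal usage
football pitch,7.0,casual football
five a side pitch,7.0,small sided football
ice rink,7.0,ice skating
rowing club,7.0,sculling
ski slope,7.0,dry slope skiing
squash court,7.3,squash
climbing wall,7.5,indoor climbing
hockey pitch,7.8,field hockey
boxing gym,7.8,sparring and bag work
athletics track,8.0,hard training typical
shinty pitch,8.0,played at vigorous intensity
gaelic football pitch,8.0,played at vigorous intensity
handball court,8.0,team handball
rugby pitch,8.3,rugby union
velodrome,10.0,track cycling
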